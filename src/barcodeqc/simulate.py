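"""Ground-truth synthetic barcode datasets.

The generator emulates the statistical structure the QC analysis assumes: a
set of species clusters whose sequences diverge little within species and a
lot between species, evolved site-independently under the Kimura
2-parameter substitution process (exact branch transition probabilities,
no discretisation), with optional injected errors mimicking the real-world
failure modes — species relabels (misidentification), cross-species
contamination, and divergent outliers.

Species history is a Yule (pure-birth) tree whose branch lengths are scaled
so the mean leaf-pair path matches the interspecific divergence target;
shallow splits are then raised to a minimum species separation so the
generated data exhibit the barcode gap the method assumes (a Yule tree
scaled only by its mean leaves many species pairs far closer than typical
barcode neighbours).  Each species leaf carries a star of sequences at half
the intraspecific target depth.  One random generator derived from the seed
drives tree shape, sequence evolution and error injection, in that order,
so runs are fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignedDataset, SeqRecord, decode
from .njtree import Node, PhyloTree


@dataclass(frozen=True)
class ErrorSpec:
    """Per-record injection probabilities for each error class."""

    relabel: float = 0.0  #: species label swapped to a random other species
    contaminate: float = 0.0  #: sequence replaced by a noisy heterospecific copy
    diverge: float = 0.0  #: extra substitutions pushed onto the sequence

    def __post_init__(self) -> None:
        rates = (self.relabel, self.contaminate, self.diverge)
        if any(r < 0 or r > 1 for r in rates):
            raise ValueError("error rates must be in [0, 1]")
        if sum(rates) > 1.0:
            raise ValueError("error rates must sum to at most 1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror typical mitochondrial barcode surveys: a few percent
    divergence at most within species, around 10% between species, and a
    transition/transversion rate ratio of 4.
    """

    n_species: int = 20
    seqs_per_species: int = 5
    seq_length: int = 924  #: sites; a typical trimmed Cytb barcode window
    kappa: float = 4.0  #: transition/transversion rate ratio
    inter_depth: float = 0.10  #: mean interspecific path-length target
    inter_floor: float = 0.10  #: minimum species-pair separation
    intra_depth: float = 0.005  #: expected intraspecific pair divergence
    diverge_depth: float = 0.15  #: extra branch length for injected outliers
    errors: ErrorSpec = field(default_factory=ErrorSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.seqs_per_species < 1 or self.seq_length < 1:
            raise ValueError("counts must be >= 1")
        if self.inter_depth <= 0 or self.intra_depth <= 0:
            raise ValueError("divergence depths must be > 0")


def species_name(i: int) -> str:
    return f"Simulatus sp{i + 1:03d}"


def _accession(k: int) -> str:
    return f"SIM{k + 1:04d}"


def simulate_species_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Yule species tree with per-species sequence stars.

    Branch lengths are scaled so the mean species-pair path equals
    ``inter_depth``; node depths are then floored at ``inter_floor / 2`` so
    no species pair sits closer than ``inter_floor``.  Each species leaf is
    expanded into ``seqs_per_species`` sequence leaves (named ``SIM0001``,
    ...) at depth ``intra_depth / 2``.  Deterministic given the generator.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_species
    # forward-time pure birth: split a uniformly chosen lineage at each event
    root = Node()
    if n == 1:
        tips = [root]
    else:
        tips = [Node(), Node()]
        root.children = list(tips)
        birth = {id(t): 0.0 for t in tips}
        t_now = 0.0
        while len(tips) < n:
            t_now += rng.exponential(1.0 / len(tips))
            k = int(rng.integers(len(tips)))
            parent = tips[k]
            parent.length = t_now - birth.pop(id(parent))
            kids = [Node(), Node()]
            parent.children = kids
            tips[k:k + 1] = kids
            for c in kids:
                birth[id(c)] = t_now
        t_now += rng.exponential(1.0 / n)
        for t in tips:
            t.length = t_now - birth[id(t)]

    # scale so mean species-pair path = inter_depth, then floor node depths
    if n > 1:
        for k_tip, sp_tip in enumerate(tips):
            sp_tip.name = f"t{k_tip}"  # temporary so path_lengths sees distinct leaves
        paths = PhyloTree(root).path_lengths()
        mean = float(np.mean(list(paths.values()))) if paths else 0.0
        factor = cfg.inter_depth / mean if mean > 0 else 1.0
        floor = cfg.inter_floor / 2.0

        def rescale(node: Node) -> tuple[float, float]:
            """Scale branches and floor each node's own depth.

            Returns (floored depth, original scaled depth); recomputing child
            branch lengths from floored depths keeps ancestors where the Yule
            draw put them, so only the too-shallow splits move.
            """
            node.length *= factor
            if node.is_leaf:
                return 0.0, 0.0
            child = [rescale(c) for c in node.children]
            orig = max(oc + c.length for (_, oc), c in zip(child, node.children))
            new = max(orig, floor)
            for (fc, _), c in zip(child, node.children):
                c.length = new - fc
            return new, orig

        rescale(root)

    # expand each species leaf into a star of sequence leaves
    k = 0
    for i, tip in enumerate(tips):
        sp = species_name(i)
        tip.name = None
        for _ in range(cfg.seqs_per_species):
            tip.children.append(Node(name=_accession(k), length=cfg.intra_depth / 2.0))
            k += 1
        tip.species = sp  # type: ignore[attr-defined] -- annotation for dataset assembly
    return PhyloTree(root)


def _k2p_branch_probs(t: float, kappa: float) -> tuple[float, float]:
    """(transition prob, per-target transversion prob) after branch length t.

    The rate matrix is normalised to one expected substitution per site per
    unit branch length: beta = 1/(kappa+2), alpha = kappa * beta.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1  # two transversion targets, this each
    return float(p_ts), float(p_tv_each)


def _evolve_branch(parent_codes: np.ndarray, t: float, kappa: float,
                   rng: np.random.Generator) -> np.ndarray:
    if t <= 0.0:
        return parent_codes.copy()
    p_ts, p_tv = _k2p_branch_probs(t, kappa)
    u = rng.random(parent_codes.shape[0])
    child = parent_codes.copy()
    # codes A=0,C=1,G=2,T=3: ^2 is the transition partner, ^1/^3 transversions
    mask_ts = u < p_ts
    mask_tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    mask_tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    child[mask_ts] ^= 2
    child[mask_tv1] ^= 1
    child[mask_tv2] ^= 3
    return child


def evolve_alignment(tree: PhyloTree, cfg: SimConfig,
                     rng: np.random.Generator | None = None) -> AlignedDataset:
    """Evolve a gap-free alignment along the tree under the K2P process.

    The root sequence is uniform over {A,C,G,T}; each branch applies the
    exact K2P transition probabilities for its length.  Leaf records take
    their species label from the star-expansion annotation on the tree (or
    their own name when absent).  Deterministic given the generator.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    root_codes = rng.integers(0, 4, size=cfg.seq_length).astype(np.uint8)
    records: list[SeqRecord] = []

    def walk(node: Node, codes: np.ndarray, species: str | None) -> None:
        species = getattr(node, "species", None) or species
        if node.is_leaf:
            records.append(SeqRecord(
                accession=node.name, species=species or node.name,
                seq=decode(codes),
            ))
            return
        for child in node.children:
            walk(child, _evolve_branch(codes, child.length, cfg.kappa, rng), species)

    walk(tree.root, root_codes, None)
    return AlignedDataset(records, frame_offset=0)


def inject_errors(
    ds: AlignedDataset, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[AlignedDataset, pd.DataFrame]:
    """Inject labelled errors and return the modified dataset plus truth table.

    Error classes (at the per-record rates in ``cfg.errors``):

    * relabel — the species label is swapped to a random other species;
    * contaminate — the sequence is replaced by a copy of a random
      heterospecific record with intraspecific-level noise added;
    * diverge — the sequence accrues ``diverge_depth`` extra substitutions.

    The truth table lists, per accession, the true species, the observed
    (possibly wrong) label, the error class (or ``none``) and a detail
    string.  Deterministic given the generator.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    er = cfg.errors
    all_species = sorted({r.species for r in ds})
    records = list(ds.records)
    truth_rows = []
    u = rng.random(len(records))
    for i, rec in enumerate(records):
        error = "none"
        detail = ""
        observed = rec.species
        if u[i] < er.relabel and len(all_species) > 1:
            error = "relabel"
            others = [s for s in all_species if s != rec.species]
            observed = others[int(rng.integers(len(others)))]
            records[i] = replace(rec, species=observed)
            detail = f"label {rec.species} -> {observed}"
        elif u[i] < er.relabel + er.contaminate:
            donors = [j for j, r2 in enumerate(ds.records) if r2.species != rec.species]
            if donors:
                error = "contaminate"
                j = donors[int(rng.integers(len(donors)))]
                donor = ds.records[j]
                noisy = _evolve_branch(ds.codes[j], cfg.intra_depth, cfg.kappa, rng)
                records[i] = replace(rec, seq=decode(noisy))
                detail = f"sequence copied from {donor.accession} ({donor.species})"
        elif u[i] < er.relabel + er.contaminate + er.diverge:
            error = "diverge"
            mutated = _evolve_branch(ds.codes[i], cfg.diverge_depth, cfg.kappa, rng)
            records[i] = replace(rec, seq=decode(mutated))
            detail = f"extra branch length {cfg.diverge_depth}"
        truth_rows.append({
            "accession": rec.accession, "true_species": rec.species,
            "observed_species": observed, "error": error, "detail": detail,
        })
    truth = pd.DataFrame(truth_rows)
    return ds.replace_records(records), truth


def assign_groups(ds: AlignedDataset, n_groups: int = 4) -> AlignedDataset:
    """Attach round-robin higher-taxon group labels (``G1`` ... ``Gk``) by species."""
    species = sorted({r.species_key for r in ds})
    group_of = {sp: f"G{(i % n_groups) + 1}" for i, sp in enumerate(species)}
    return ds.replace_records([replace(r, group=group_of[r.species_key]) for r in ds])


def simulate_dataset(cfg: SimConfig) -> tuple[AlignedDataset, pd.DataFrame, PhyloTree]:
    """Tree + alignment + injected errors in one reproducible call.

    A single random stream derived from ``cfg.seed`` is consumed in the
    order: species tree, sequence evolution, error injection.  Returns the
    (possibly corrupted) dataset with group labels, the truth table, and
    the generating tree.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_species_tree(cfg, rng)
    clean = evolve_alignment(tree, cfg, rng)
    corrupted, truth = inject_errors(clean, cfg, rng)
    return assign_groups(corrupted), truth, tree


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
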