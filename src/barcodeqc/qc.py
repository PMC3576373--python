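"""Barcode-gap quality control.

DNA barcoding rests on the gap between intraspecific divergence (mostly
below 1–2%) and interspecific divergence (mostly above 8–10%).  A sequence
that sits far from every conspecific (*deep intraspecific divergence*) or
very close to a heterospecific (*shallow interspecific divergence*) breaks
that gap; a sequence showing both at once — the *paradox* — is the primary
signature of a mislabeled, contaminated or misidentified record (it may
also reflect an outdated taxonomy, so flags are advisory, never deletions).

Flags are driven by nearest-neighbour distances: a single contaminant pair
is evidence no matter how many well-behaved conspecifics exist.  Evidence is
reported as min–max percentage ranges against the implicated species.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .alignment import AlignedDataset
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

FlagType = Literal["deep_intra", "shallow_inter", "paradox", "identical_cross_species"]


@dataclass(frozen=True)
class FlagConfig:
    """Thresholds separating ordinary from suspicious divergences.

    No single cutoff exists in nature; intraspecific divergence rarely
    exceeds 5% while interspecific divergence usually exceeds 8%, so 0.05 is
    a conservative default on both sides.  Both thresholds are echoed into
    every report header.
    """

    t_deep: float = 0.05  #: nearest conspecific farther than this = deep
    t_shallow: float = 0.05  #: nearest heterospecific closer than this = shallow
    t_identical: float = 0.0  #: at/below this a cross-species pair counts as identical

    def __post_init__(self) -> None:
        if self.t_deep < 0 or self.t_shallow < 0 or self.t_identical < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class QCFlag:
    """One advisory flag for one accession.

    ``evidence`` holds the distance ranges that triggered the flag (as
    fractions, not percentages): ``intra_min``/``intra_max`` over defined
    conspecific distances, ``inter_min``/``inter_max`` over defined
    distances to the implicated partner species.
    """

    accession: str
    species: str
    flag_type: FlagType
    evidence: dict[str, float]
    partner_species: tuple[str, ...] = ()

    def describe(self) -> str:
        """Human-readable reason in the min–max percentage style."""
        parts = []
        if self.flag_type in ("shallow_inter", "paradox", "identical_cross_species"):
            rng = _pct_range(self.evidence["inter_min"], self.evidence["inter_max"])
            partners = ", ".join(self.partner_species)
            kind = "Identical sequence shared" if self.flag_type == "identical_cross_species" \
                else "Shallow interspecific divergence"
            parts.append(f"{kind} with {partners} ({rng})")
        if self.flag_type in ("deep_intra", "paradox"):
            rng = _pct_range(self.evidence["intra_min"], self.evidence["intra_max"])
            parts.append(f"deep intraspecific divergence ({rng})")
        return " but ".join(parts)


def _pct_range(lo: float, hi: float) -> str:
    if abs(hi - lo) < 5e-4:
        return f"{100 * lo:.1f}%"
    return f"{100 * lo:.1f}%–{100 * hi:.1f}%"


@dataclass
class DivergencePartition:
    """Defined pairwise distances split into intra- and interspecific sets."""

    intra: dict[str, list[tuple[str, str, float]]]
    inter: dict[frozenset[str], list[tuple[str, str, float]]]
    bin_width: float = 0.01

    @property
    def intra_values(self) -> np.ndarray:
        vals = [d for pairs in self.intra.values() for _, _, d in pairs]
        return np.array(vals, dtype=float)

    @property
    def inter_values(self) -> np.ndarray:
        vals = [d for pairs in self.inter.values() for _, _, d in pairs]
        return np.array(vals, dtype=float)

    def histogram(self) -> pd.DataFrame:
        """Binned counts for both classes: bin_low, bin_high, count, class."""
        rows = []
        for cls, vals in (("intra", self.intra_values), ("inter", self.inter_values)):
            if vals.size == 0:
                continue
            top = max(self.bin_width, float(vals.max()))
            nbins = int(np.ceil(top / self.bin_width)) or 1
            edges = np.arange(nbins + 1) * self.bin_width
            counts, _ = np.histogram(vals, bins=edges)
            for k in range(nbins):
                rows.append({"bin_low": edges[k], "bin_high": edges[k + 1],
                             "count": int(counts[k]), "class": cls})
        return pd.DataFrame(rows)


def partition_divergences(
    dm: DistanceMatrix, records: AlignedDataset, bin_width: float = 0.01
) -> DivergencePartition:
    """Assign every defined pair to the intra- or interspecific set.

    Species identity is decided at species rank (subspecies epithets
    ignored).  Species represented by a single record contribute no
    intraspecific pairs; this is logged, not an error.
    """
    species = records.species
    if records.accessions != dm.labels:
        raise ValueError("distance matrix labels do not match dataset accessions")
    intra: dict[str, list] = defaultdict(list)
    inter: dict[frozenset[str], list] = defaultdict(list)
    n = len(dm.labels)
    for i in range(n):
        for j in range(i + 1, n):
            if not dm.defined[i, j]:
                continue
            d = float(dm.d[i, j])
            pair = (dm.labels[i], dm.labels[j], d)
            if species[i] == species[j]:
                intra[species[i]].append(pair)
            else:
                inter[frozenset((species[i], species[j]))].append(pair)
    singletons = [sp for sp, cnt in pd.Series(species).value_counts().items() if cnt == 1]
    if singletons:
        logger.info("%d singleton species contribute no intraspecific pairs", len(singletons))
    return DivergencePartition(intra=dict(intra), inter=dict(inter), bin_width=bin_width)


@dataclass
class FlagReport:
    """Flags plus the records that could not be evaluated at all."""

    flags: list[QCFlag]
    unevaluable: list[str]  #: accessions whose distances are all undefined
    config: FlagConfig

    def flagged_accessions(self, flag_types: Iterable[FlagType] | None = None) -> set[str]:
        wanted = set(flag_types) if flag_types is not None else None
        return {f.accession for f in self.flags if wanted is None or f.flag_type in wanted}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"accession": f.accession, "species": f.species, "flag_type": f.flag_type,
             "evidence": f.describe(), "partner_species": "; ".join(f.partner_species)}
            for f in self.flags
        ]
        return pd.DataFrame(rows, columns=["accession", "species", "flag_type",
                                           "evidence", "partner_species"])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write(f"# t_deep={self.config.t_deep} t_shallow={self.config.t_shallow} "
                      f"t_identical={self.config.t_identical}\n")
            self.to_frame().to_csv(out, sep="\t", index=False)
            if self.unevaluable:
                out.write("# unevaluable\t" + "\t".join(self.unevaluable) + "\n")

    def write_markdown(self, path: str | Path) -> None:
        """Two-column table: flagged sequence(s) | reason."""
        frame = self.to_frame()
        with open(path, "w") as out:
            out.write(f"Thresholds: t_deep={self.config.t_deep}, "
                      f"t_shallow={self.config.t_shallow}, "
                      f"t_identical={self.config.t_identical}\n\n")
            out.write("| Potential error sequences | Reasons |\n|---|---|\n")
            for _, row in frame.iterrows():
                out.write(f"| {row.accession} *{row.species}* | {row.evidence} |\n")
            if self.unevaluable:
                out.write("\nUnevaluable (all distances undefined): "
                          + ", ".join(self.unevaluable) + "\n")


def flag_potential_errors(
    dm: DistanceMatrix, records: AlignedDataset, cfg: FlagConfig = FlagConfig()
) -> FlagReport:
    """Flag sequences whose divergences break the barcode gap.

    For every sequence the distance to its nearest conspecific and nearest
    heterospecific (over defined entries only) drives the decision:

    * ``deep_intra``   — nearest conspecific farther than ``t_deep``;
    * ``shallow_inter`` — nearest heterospecific closer than ``t_shallow``;
    * ``paradox``       — both at once (emitted instead of the two parts);
    * ``identical_cross_species`` — a heterospecific at distance
      ``<= t_identical`` (additional to the above).

    Singleton species have no intraspecific evidence and can only receive
    the interspecific flags.  Sequences with no defined distance at all are
    returned separately as unevaluable.
    """
    if records.accessions != dm.labels:
        raise ValueError("distance matrix labels do not match dataset accessions")
    species = np.array(records.species)
    n = len(dm.labels)
    flags: list[QCFlag] = []
    unevaluable: list[str] = []
    d = dm.d
    defined = dm.defined.copy()
    np.fill_diagonal(defined, False)  # self-distances are not evidence

    for i in range(n):
        same = (species == species[i])
        same[i] = False
        intra_ok = same & defined[i]
        inter_ok = (~same) & defined[i]
        inter_ok[i] = False
        if not intra_ok.any() and not inter_ok.any():
            unevaluable.append(dm.labels[i])
            continue

        intra_min = intra_max = None
        if intra_ok.any():
            vals = d[i, intra_ok]
            intra_min, intra_max = float(vals.min()), float(vals.max())

        inter_min = None
        partner = None
        if inter_ok.any():
            vals = d[i, inter_ok]
            inter_min = float(vals.min())
            partner = species[np.flatnonzero(inter_ok)[int(np.argmin(vals))]]
            partner_mask = inter_ok & (species == partner)
            pvals = d[i, partner_mask]
            partner_min, partner_max = float(pvals.min()), float(pvals.max())

        deep = intra_min is not None and intra_min > cfg.t_deep
        shallow = inter_min is not None and inter_min < cfg.t_shallow

        if deep and shallow:
            flags.append(QCFlag(
                accession=dm.labels[i], species=species[i], flag_type="paradox",
                evidence={"intra_min": intra_min, "intra_max": intra_max,
                          "inter_min": partner_min, "inter_max": partner_max},
                partner_species=(partner,),
            ))
        elif deep:
            flags.append(QCFlag(
                accession=dm.labels[i], species=species[i], flag_type="deep_intra",
                evidence={"intra_min": intra_min, "intra_max": intra_max},
            ))
        elif shallow:
            flags.append(QCFlag(
                accession=dm.labels[i], species=species[i], flag_type="shallow_inter",
                evidence={"inter_min": partner_min, "inter_max": partner_max},
                partner_species=(partner,),
            ))

        if inter_min is not None and inter_min <= cfg.t_identical:
            zero_mask = inter_ok & (d[i] <= cfg.t_identical)
            partners = tuple(sorted(set(species[zero_mask])))
            zvals = d[i, zero_mask]
            flags.append(QCFlag(
                accession=dm.labels[i], species=species[i],
                flag_type="identical_cross_species",
                evidence={"inter_min": float(zvals.min()), "inter_max": float(zvals.max())},
                partner_species=partners,
            ))
    return FlagReport(flags=flags, unevaluable=unevaluable, config=cfg)


def haplotype_collapse(ds: AlignedDataset) -> dict[str, tuple[int, int]]:
    """Per-species record and haplotype counts.

    Records identical over their shared defined sites merge into one
    haplotype (union–find over the pairwise compatibility relation, which
    lets partial sequences join the haplotype of their full-length twins).
    """
    codes = ds.codes
    species = ds.species
    by_species: dict[str, list[int]] = defaultdict(list)
    for i, sp in enumerate(species):
        by_species[sp].append(i)

    out: dict[str, tuple[int, int]] = {}
    for sp, idx in by_species.items():
        parent = {i: i for i in idx}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a_pos, i in enumerate(idx):
            for j in idx[a_pos + 1:]:
                both = (codes[i] < 4) & (codes[j] < 4)
                if not np.any(both & (codes[i] != codes[j])):
                    parent[find(i)] = find(j)
        out[sp] = (len(idx), len({find(i) for i in idx}))
    return out


def error_ratio_by_group(
    flags: Iterable[QCFlag], records: AlignedDataset
) -> pd.DataFrame:
    """Fraction of flagged accessions per higher-taxon group, as percentages.

    Counts distinct flagged accessions (a sequence with several flags counts
    once); pass a pre-filtered flag collection to restrict to particular
    flag types.  Records without a group label are pooled under ``(none)``.
    """
    flagged = {f.accession for f in flags}
    rows: dict[str, dict[str, int]] = defaultdict(lambda: {"n_records": 0, "n_flagged": 0})
    for rec in records:
        group = rec.group or "(none)"
        rows[group]["n_records"] += 1
        if rec.accession in flagged:
            rows[group]["n_flagged"] += 1
    frame = pd.DataFrame(
        [{"group": g, **v, "error_ratio_pct": 100.0 * v["n_flagged"] / v["n_records"]}
         for g, v in sorted(rows.items())]
    )
    return frame
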