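"""Neighbor-joining summary trees.

The tree is a diagnostic summary of the patterning of divergences among
species, not a phylogenetic claim: NJ is exact on additive matrices and fast
enough to rebuild hundreds of bootstrap replicates, which is all the QC
workflow needs.

Conventions: the tree is unrooted, represented with a trifurcating root;
ties in the joining criterion are broken by the lowest (row, column) index
pair; negative branch lengths arising from NJ arithmetic are set to zero
with the difference transferred to the adjacent branch of the join, so all
reported lengths are non-negative.  Bootstrap supports are integer
percentages of replicates containing the same bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np

from .alignment import AlignedDataset
from .distances import DistanceMatrix, _pairwise_arrays, distance_matrix

logger = logging.getLogger(__name__)


@dataclass
class Node:
    """Tree node; leaves carry a name, internal nodes may carry a support."""

    name: str | None = None
    length: float = 0.0  #: branch length to the parent (substitutions/site)
    support: int | None = None  #: bootstrap percentage, internal nodes only
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class PhyloTree:
    """Unrooted tree with branch lengths, serialisable to Newick."""

    def __init__(self, root: Node):
        self.root = root

    @property
    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else str(self.root.support)
        return f"({inner}){label};"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised to the side not containing
        the alphabetically first leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        n = len(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < n - 1:
                side = all_leaves - below if ref in below else below
                out.add(side)
            return below

        walk(self.root)
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths keyed by sorted name pairs."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            sub = [walk(c) for c in node.children]
            for k, c in enumerate(node.children):
                for name in sub[k]:
                    sub[k][name] += c.length
            for a, b in combinations(range(len(sub)), 2):
                for na, da in sub[a].items():
                    for nb, db in sub[b].items():
                        dists[tuple(sorted((na, nb)))] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self.root)
        return dists


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei neighbor joining on a fully defined distance matrix.

    Undefined entries are a hard error: drop them first with
    :func:`barcodeqc.distances.prune_undefined` (or impute explicitly).
    """
    if not dm.defined.all():
        raise ValueError(
            "distance matrix has undefined entries; run prune_undefined() "
            "or drop/impute the affected records before building a tree"
        )
    n = len(dm.labels)
    if n < 2:
        raise ValueError("neighbor joining needs at least 2 records")
    nodes = [Node(name=lab) for lab in dm.labels]
    if n == 2:
        half = float(dm.d[0, 1]) / 2.0
        for nd in nodes:
            nd.length = half
        return PhyloTree(Node(children=nodes))

    D = dm.d.astype(float).copy()
    active = list(nodes)
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # first minimum -> lowest (row, col) pair
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        active[i].length = li
        active[j].length = lj
        parent = Node(children=[active[i], active[j]])
        dnew = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[k] for k in keep] + [parent]

    a, b, c = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    lens = [la, lb, lc]
    for k in range(3):  # transfer any negative onto the next branch around
        if lens[k] < 0.0:
            lens[(k + 1) % 3] += lens[k]
            lens[k] = 0.0
    a.length, b.length, c.length = lens
    return PhyloTree(Node(children=[a, b, c]))


def to_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths; supports as internal-node labels."""
    return tree.newick()


def from_newick(text: str) -> PhyloTree:
    """Parse Newick text (internal labels interpreted as supports)."""
    dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        node = Node(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=float(dnode.edge.length or 0.0),
        )
        if dnode.label is not None and not dnode.is_leaf():
            try:
                node.support = int(round(float(dnode.label)))
            except ValueError:
                node.name = dnode.label
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(convert(dt.seed_node))


@dataclass
class BootstrapResult:
    """NJ tree with bipartition supports plus replicate bookkeeping."""

    tree: PhyloTree
    reps_completed: int
    reps_skipped: int  #: replicates discarded for containing undefined distances


def bootstrap_support(
    ds: AlignedDataset,
    reps: int = 1000,
    seed: int = 0,
    min_overlap: int | None = None,
) -> BootstrapResult:
    """Column-resampling bootstrap supports for the full-data NJ tree.

    Each replicate resamples alignment columns with replacement, rebuilds the
    distance matrix and NJ tree, and scores which full-data bipartitions it
    contains.  Replicates with any undefined distance are skipped and
    counted.  Deterministic given ``seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if min_overlap is None:
        min_overlap = max(1, ds.length // 3)
    dm = distance_matrix(ds, min_overlap=min_overlap)
    if not dm.defined.all():
        raise ValueError("full dataset has undefined distances; prune records first")
    tree = neighbor_joining(dm)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    labels = ds.accessions
    skipped = 0
    for _ in range(reps):
        cols = rng.integers(0, ds.length, size=ds.length)
        d, ok, ts, tv, ns = _pairwise_arrays(ds.codes[:, cols], min_overlap)
        if not ok.all():
            skipped += 1
            continue
        rep_dm = DistanceMatrix(labels=labels, d=d, defined=ok, ts=ts, tv=tv,
                                n_sites=ns, min_overlap_used=min_overlap)
        rep_bps = neighbor_joining(rep_dm).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    completed = reps - skipped
    if skipped:
        logger.info("bootstrap: skipped %d/%d replicates with undefined distances", skipped, reps)
    if completed == 0:
        raise ValueError("every bootstrap replicate had undefined distances")

    all_leaves = frozenset(tree.leaf_names)
    ref = min(all_leaves)
    n = len(all_leaves)

    def annotate(node: Node, below: frozenset[str]) -> None:
        if node is not tree.root and not node.is_leaf and 1 < len(below) < n - 1:
            side = all_leaves - below if ref in below else below
            node.support = int(round(100.0 * counts[side] / completed))

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        annotate(node, below)
        return below

    walk(tree.root)
    return BootstrapResult(tree=tree, reps_completed=completed, reps_skipped=skipped)
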