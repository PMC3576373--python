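import itertools

import numpy as np
import pytest

from barcodeqc import AlignedDataset, SeqRecord
from barcodeqc.distances import DistanceMatrix
from barcodeqc.njtree import Node, PhyloTree
from barcodeqc.simulate import ErrorSpec, SimConfig, simulate_dataset


@pytest.fixture
def toy_ds() -> AlignedDataset:
    """Two species, two records each, 12 gap-free sites."""
    return AlignedDataset(
        [
            SeqRecord("A1", "Genus alpha", "ACGTACGTACGT"),
            SeqRecord("A2", "Genus alpha", "ACGTACGTACGA"),
            SeqRecord("B1", "Genus beta", "ACGTTCGAACGT"),
            SeqRecord("B2", "Genus beta", "ACGTTCGAACTT"),
        ]
    )


@pytest.fixture(scope="session")
def sim_clean():
    """Default synthetic dataset without injected errors (seed 0)."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_with_errors():
    """Default synthetic dataset with 5% relabels + 2% contaminations (seed 0)."""
    cfg = SimConfig(seed=0, errors=ErrorSpec(relabel=0.05, contaminate=0.02))
    return simulate_dataset(cfg)


def matrix_from_tree(tree: PhyloTree) -> DistanceMatrix:
    """Additive distance matrix of a tree's leaf-to-leaf path lengths."""
    pl = tree.path_lengths()
    labels = sorted(tree.leaf_names)
    m = len(labels)
    D = np.zeros((m, m))
    for i, j in itertools.combinations(range(m), 2):
        D[i, j] = D[j, i] = pl[tuple(sorted((labels[i], labels[j])))]
    return DistanceMatrix(
        labels=labels, d=D, defined=np.ones((m, m), bool),
        ts=np.zeros((m, m), int), tv=np.zeros((m, m), int),
        n_sites=np.full((m, m), 1000), min_overlap_used=1,
    )


def matrix_from_values(labels, pairs) -> DistanceMatrix:
    """Distance matrix from explicit {(a, b): d} values (symmetric fill)."""
    idx = {lab: i for i, lab in enumerate(labels)}
    m = len(labels)
    D = np.zeros((m, m))
    for (a, b), d in pairs.items():
        D[idx[a], idx[b]] = D[idx[b], idx[a]] = d
    return DistanceMatrix(
        labels=list(labels), d=D, defined=np.ones((m, m), bool),
        ts=np.zeros((m, m), int), tv=np.zeros((m, m), int),
        n_sites=np.full((m, m), 1000), min_overlap_used=1,
    )


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random unrooted binary tree with branch lengths in [0.05, 1]."""
    nodes = [Node(name=f"L{i}", length=float(rng.uniform(0.05, 1.0))) for i in range(3)]
    root = Node(children=nodes)

    def edges(node, acc):
        for c in node.children:
            acc.append((node, c))
            edges(c, acc)
        return acc

    for i in range(3, n_leaves):
        es = edges(root, [])
        parent, child = es[rng.integers(len(es))]
        split = float(rng.uniform(0.2, 0.8))
        mid = Node(length=child.length * split)
        child.length *= 1.0 - split
        parent.children[parent.children.index(child)] = mid
        mid.children = [child, Node(name=f"L{i}", length=float(rng.uniform(0.05, 1.0)))]
    return PhyloTree(root)
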