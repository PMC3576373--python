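import numpy as np
import pytest

from barcodeqc import AlignedDataset, SeqRecord
from barcodeqc.distances import distance_matrix
from barcodeqc.njtree import (
    Node,
    PhyloTree,
    bootstrap_support,
    from_newick,
    neighbor_joining,
    to_newick,
)
from barcodeqc.simulate import SimConfig, simulate_dataset

from conftest import matrix_from_tree, matrix_from_values, random_binary_tree


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = matrix_from_values(["A", "B"], {("A", "B"): 0.1})
        tree = neighbor_joining(dm)
        assert tree.path_lengths()[("A", "B")] == pytest.approx(0.1)

    def test_three_taxa_closed_form(self):
        d = {("A", "B"): 0.3, ("A", "C"): 0.5, ("B", "C"): 0.6}
        tree = neighbor_joining(matrix_from_values(["A", "B", "C"], d))
        # leaf edge to A = (d_ab + d_ac - d_bc) / 2
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_four_taxon_additive_recovery(self):
        # ((A,B),(C,D)) with distinct branch lengths; matrix built by hand
        tree = PhyloTree(Node(children=[
            Node(children=[Node(name="A", length=0.1), Node(name="B", length=0.2)],
                 length=0.05),
            Node(name="C", length=0.3),
            Node(name="D", length=0.4),
        ]))
        rec = neighbor_joining(matrix_from_tree(tree))
        assert rec.bipartitions() == tree.bipartitions() == {frozenset({"C", "D"})}
        for pair, d in tree.path_lengths().items():
            assert rec.path_lengths()[pair] == pytest.approx(d, abs=1e-12)

    def test_additive_recovery_many_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tree = random_binary_tree(rng, int(rng.integers(5, 9)))
            rec = neighbor_joining(matrix_from_tree(tree))
            assert rec.bipartitions() == tree.bipartitions()
            pl, pl_rec = tree.path_lengths(), rec.path_lengths()
            assert max(abs(pl_rec[k] - pl[k]) for k in pl) < 1e-9

    def test_equidistant_matrix_tie_break(self):
        labels = ["A", "B", "C", "D"]
        d = {(a, b): 0.2 for i, a in enumerate(labels) for b in labels[i + 1:]}
        tree = neighbor_joining(matrix_from_values(labels, d))
        # lowest-index pair joins first -> A,B form the internal edge
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        total = sum(n.length for n in _all_nodes(tree.root))
        # star-like completion: four leaf edges of 0.1, internal edge 0
        assert total == pytest.approx(0.4)

    def test_agrees_with_skbio_on_noisy_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        tree = random_binary_tree(rng, 8)
        dm = matrix_from_tree(tree)
        noisy = dm.d + rng.normal(0, 0.01, dm.d.shape)
        noisy = np.triu(noisy, 1)
        dm.d = noisy + noisy.T
        mine = neighbor_joining(dm)
        ref = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.labels))
        ref_bps = set()
        n = len(dm.labels)
        refleaf = min(dm.labels)
        for node in ref.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                ref_bps.add(frozenset(dm.labels) - below if refleaf in below else below)
        assert mine.bipartitions() == ref_bps

    def test_negative_lengths_adjusted_to_zero(self):
        d = {("A", "B"): 0.1, ("A", "C"): 0.1, ("B", "C"): 0.4}  # violates additivity
        tree = neighbor_joining(matrix_from_values(["A", "B", "C"], d))
        assert all(n.length >= 0 for n in _all_nodes(tree.root))

    def test_undefined_entries_rejected(self):
        ds = AlignedDataset([SeqRecord("X", "G s", "ACGT----"),
                             SeqRecord("Y", "G s", "----ACGT"),
                             SeqRecord("Z", "G s", "ACGTACGT")])
        dm = distance_matrix(ds, min_overlap=1)
        with pytest.raises(ValueError, match="prune_undefined"):
            neighbor_joining(dm)


def _all_nodes(node):
    yield node
    for c in node.children:
        yield from _all_nodes(c)


class TestNewick:
    def test_two_leaf_shape(self):
        dm = matrix_from_values(["A", "B"], {("A", "B"): 0.1})
        assert to_newick(neighbor_joining(dm)) == "(A:0.05,B:0.05);"

    def test_round_trip_isomorphic(self):
        rng = np.random.default_rng(11)
        tree = random_binary_tree(rng, 10)
        back = from_newick(to_newick(tree))
        assert back.bipartitions() == tree.bipartitions()
        pl, pl_back = tree.path_lengths(), back.path_lengths()
        assert max(abs(pl_back[k] - pl[k]) for k in pl) < 1e-9

    def test_supports_appear_after_parentheses(self):
        tree = PhyloTree(Node(children=[
            Node(children=[Node(name="A", length=0.1), Node(name="B", length=0.1)],
                 length=0.05, support=97),
            Node(name="C", length=0.2),
            Node(name="D", length=0.2),
        ]))
        text = to_newick(tree)
        assert ")97:" in text
        assert from_newick(text).root.children[0].support == 97


class TestBootstrap:
    def test_clean_two_clade_support(self):
        cfg = SimConfig(n_species=2, seqs_per_species=4, seq_length=600, seed=5)
        ds, _, _ = simulate_dataset(cfg)
        result = bootstrap_support(ds, reps=100, seed=5)
        clade = frozenset(a for a, sp in zip(ds.accessions, ds.species)
                          if sp != min(ds.species))
        supports = {n.support for n in _all_nodes(result.tree.root)
                    if n.support is not None}
        # the species bipartition is the deepest split; all supports spanning
        # it should be near-certain
        bps = result.tree.bipartitions()
        assert clade in bps or (frozenset(ds.accessions) - clade) in bps
        assert max(supports) >= 95

    def test_same_seed_reproducible(self, toy_ds):
        r1 = bootstrap_support(toy_ds, reps=30, seed=9, min_overlap=1)
        r2 = bootstrap_support(toy_ds, reps=30, seed=9, min_overlap=1)
        assert to_newick(r1.tree) == to_newick(r2.tree)

    def test_supports_invariant_to_leaf_order(self, toy_ds):
        rev = AlignedDataset(list(reversed(toy_ds.records)))
        r1 = bootstrap_support(toy_ds, reps=50, seed=4, min_overlap=1)
        r2 = bootstrap_support(rev, reps=50, seed=4, min_overlap=1)

        def support_by_bipartition(tree):
            out = {}
            all_leaves = frozenset(tree.leaf_names)
            ref = min(all_leaves)
            n = len(all_leaves)

            def walk(node):
                below = frozenset([node.name]) if node.is_leaf else \
                    frozenset().union(*(walk(c) for c in node.children))
                if node.support is not None and 1 < len(below) < n - 1:
                    side = all_leaves - below if ref in below else below
                    out[side] = node.support
                return below

            walk(tree.root)
            return out

        assert support_by_bipartition(r1.tree) == support_by_bipartition(r2.tree)

    def test_zero_divergence_collapses_or_full_support(self):
        ds = AlignedDataset([SeqRecord(f"R{i}", "G s", "ACGTACGTAC") for i in range(4)])
        result = bootstrap_support(ds, reps=10, seed=1, min_overlap=1)
        assert all(n.support in (None, 100) for n in _all_nodes(result.tree.root))
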