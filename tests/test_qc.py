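import numpy as np
import pytest

from barcodeqc import AlignedDataset, SeqRecord
from barcodeqc.distances import distance_matrix
from barcodeqc.qc import (
    FlagConfig,
    error_ratio_by_group,
    flag_potential_errors,
    haplotype_collapse,
    partition_divergences,
)

from conftest import matrix_from_values


def _records(specs):
    """Records with dummy equal sequences; distances supplied separately."""
    return AlignedDataset([SeqRecord(acc, sp, "ACGTACGTACGT", group=grp)
                           for acc, sp, grp in specs])


class TestPartition:
    def test_pair_counting(self, toy_ds):
        dm = distance_matrix(toy_ds, min_overlap=1)
        part = partition_divergences(dm, toy_ds)
        assert len(part.intra_values) == 2
        assert len(part.inter_values) == 4

    def test_single_species_has_no_inter(self):
        ds = _records([("X", "Genus alpha", None), ("Y", "Genus alpha", None)])
        part = partition_divergences(distance_matrix(ds, min_overlap=1), ds)
        assert len(part.inter_values) == 0 and len(part.intra_values) == 1

    def test_conservation(self, sim_clean):
        ds, _, _ = sim_clean
        dm = distance_matrix(ds)
        part = partition_divergences(dm, ds)
        n = len(ds)
        off_diag_defined = (dm.defined.sum() - n) // 2
        assert len(part.intra_values) + len(part.inter_values) == off_diag_defined

    def test_gap_on_clean_synthetic_data(self, sim_clean):
        ds, _, _ = sim_clean
        part = partition_divergences(distance_matrix(ds), ds)
        assert (part.intra_values < 0.02).mean() >= 0.90
        assert (part.inter_values > 0.08).mean() >= 0.90

    def test_subspecies_grouped_at_species_rank(self):
        ds = _records([("X", "Genus alpha one", None), ("Y", "Genus alpha two", None)])
        part = partition_divergences(distance_matrix(ds, min_overlap=1), ds)
        assert len(part.intra_values) == 1 and len(part.inter_values) == 0

    def test_histogram_totals(self, toy_ds):
        part = partition_divergences(distance_matrix(toy_ds, min_overlap=1), toy_ds)
        hist = part.histogram()
        assert hist.loc[hist["class"] == "intra", "count"].sum() == 2
        assert hist.loc[hist["class"] == "inter", "count"].sum() == 4


class TestFlagging:
    def test_paradox_fires_when_both_conditions_hold(self):
        ds = _records([("A1", "Genus alpha", None), ("A2", "Genus alpha", None),
                       ("B1", "Genus beta", None)])
        dm = matrix_from_values(["A1", "A2", "B1"],
                                {("A1", "A2"): 0.15, ("A1", "B1"): 0.005,
                                 ("A2", "B1"): 0.15})
        report = flag_potential_errors(dm, ds)
        flags = {f.accession: f for f in report.flags}
        assert flags["A1"].flag_type == "paradox"
        assert flags["A1"].partner_species == ("Genus beta",)

    def test_clean_dataset_no_flags(self, sim_clean):
        ds, _, _ = sim_clean
        report = flag_potential_errors(distance_matrix(ds), ds)
        assert report.flags == [] and report.unevaluable == []

    def test_mislabeled_turtle_paradox_from_published_divergences(self):
        """The deep-intra/shallow-inter paradox on real reported values:
        a softshell turtle sequence 15.4-16.0% from its conspecifics but
        only 1.6% from a heterospecific is flagged with both ranges."""
        ds = _records([
            ("AY743417", "Palea steindachneri", None),
            ("AY259552", "Palea steindachneri", None),
            ("NC_013841", "Palea steindachneri", None),
            ("JF719809", "Pelochelys cantorii", None),
        ])
        dm = matrix_from_values(
            ["AY743417", "AY259552", "NC_013841", "JF719809"],
            {("AY743417", "AY259552"): 0.154, ("AY743417", "NC_013841"): 0.160,
             ("AY743417", "JF719809"): 0.016, ("AY259552", "NC_013841"): 0.005,
             ("AY259552", "JF719809"): 0.190, ("NC_013841", "JF719809"): 0.192})
        report = flag_potential_errors(dm, ds)
        flags = {f.accession: f for f in report.flags}
        f = flags["AY743417"]
        assert f.flag_type == "paradox"
        assert f.partner_species == ("Pelochelys cantorii",)
        assert f.evidence["intra_min"] == pytest.approx(0.154)
        assert f.evidence["intra_max"] == pytest.approx(0.160)
        assert f.evidence["inter_min"] == pytest.approx(0.016)
        assert "15.4%–16.0%" in f.describe()
        assert "1.6%" in f.describe()

    def test_deep_intra_only(self):
        ds = _records([("A1", "Genus alpha", None), ("A2", "Genus alpha", None),
                       ("B1", "Genus beta", None)])
        dm = matrix_from_values(["A1", "A2", "B1"],
                                {("A1", "A2"): 0.12, ("A1", "B1"): 0.2,
                                 ("A2", "B1"): 0.2})
        report = flag_potential_errors(dm, ds)
        assert {f.flag_type for f in report.flags} == {"deep_intra"}
        assert report.flagged_accessions() == {"A1", "A2"}

    def test_singleton_species_only_inter_flags(self):
        ds = _records([("A1", "Genus alpha", None), ("B1", "Genus beta", None)])
        dm = matrix_from_values(["A1", "B1"], {("A1", "B1"): 0.01})
        report = flag_potential_errors(dm, ds)
        assert all(f.flag_type == "shallow_inter" for f in report.flags)
        assert report.flagged_accessions() == {"A1", "B1"}

    def test_identical_cross_species_symmetric(self):
        ds = _records([("A1", "Genus alpha", None), ("B1", "Genus beta", None),
                       ("B2", "Genus beta", None)])
        dm = matrix_from_values(["A1", "B1", "B2"],
                                {("A1", "B1"): 0.0, ("A1", "B2"): 0.02,
                                 ("B1", "B2"): 0.02})
        report = flag_potential_errors(dm, ds)
        identical = {f.accession: f for f in report.flags
                     if f.flag_type == "identical_cross_species"}
        assert set(identical) == {"A1", "B1"}
        assert identical["A1"].partner_species == ("Genus beta",)
        assert identical["B1"].partner_species == ("Genus alpha",)

    def test_flag_monotonicity_in_thresholds(self, sim_with_errors):
        ds, _, _ = sim_with_errors
        dm = distance_matrix(ds)
        lo = flag_potential_errors(dm, ds, FlagConfig(t_deep=0.05, t_shallow=0.03))
        hi = flag_potential_errors(dm, ds, FlagConfig(t_deep=0.05, t_shallow=0.06))
        shallow_lo = lo.flagged_accessions(["shallow_inter", "paradox"])
        shallow_hi = hi.flagged_accessions(["shallow_inter", "paradox"])
        assert shallow_lo <= shallow_hi
        deep_lo = flag_potential_errors(dm, ds, FlagConfig(t_deep=0.03)) \
            .flagged_accessions(["deep_intra", "paradox"])
        deep_hi = flag_potential_errors(dm, ds, FlagConfig(t_deep=0.08)) \
            .flagged_accessions(["deep_intra", "paradox"])
        assert deep_hi <= deep_lo

    def test_unevaluable_reported(self):
        ds = AlignedDataset([SeqRecord("X", "G s", "ACGT----"),
                             SeqRecord("Y", "G s", "----ACGT"),
                             SeqRecord("Z", "G t", "NNNNNNNN")])
        dm = distance_matrix(ds, min_overlap=1)
        report = flag_potential_errors(dm, ds)
        assert "Z" in report.unevaluable

    def test_report_writers(self, tmp_path):
        ds = _records([("A1", "Genus alpha", None), ("A2", "Genus alpha", None),
                       ("B1", "Genus beta", None)])
        dm = matrix_from_values(["A1", "A2", "B1"],
                                {("A1", "A2"): 0.15, ("A1", "B1"): 0.005,
                                 ("A2", "B1"): 0.15})
        report = flag_potential_errors(dm, ds)
        tsv, md = tmp_path / "flags.tsv", tmp_path / "flags.md"
        report.write_tsv(tsv)
        report.write_markdown(md)
        assert "t_deep=0.05" in tsv.read_text().splitlines()[0]
        assert "| A1 *Genus alpha* |" in md.read_text()


class TestHaplotypes:
    def test_shared_haplotype_counts(self):
        ds = AlignedDataset([SeqRecord(f"I{i}", "Indotestudo forstenii", "ACGTACGT")
                             for i in range(16)])
        assert haplotype_collapse(ds) == {"Indotestudo forstenii": (16, 1)}

    def test_two_of_three_identical(self):
        ds = AlignedDataset([SeqRecord("X", "G s", "ACGTACGT"),
                             SeqRecord("Y", "G s", "ACGTACGT"),
                             SeqRecord("Z", "G s", "ACGTACGA")])
        assert haplotype_collapse(ds) == {"G s": (3, 2)}

    def test_mutually_gapped_sites_ignored(self):
        ds = AlignedDataset([SeqRecord("X", "G s", "ACGT--GT"),
                             SeqRecord("Y", "G s", "ACGTAC--")])
        assert haplotype_collapse(ds) == {"G s": (2, 1)}

    def test_species_kept_separate(self):
        ds = AlignedDataset([SeqRecord("X", "G s", "ACGTACGT"),
                             SeqRecord("Y", "G t", "ACGTACGT")])
        assert haplotype_collapse(ds) == {"G s": (1, 1), "G t": (1, 1)}


class TestErrorRatios:
    def test_ratio_arithmetic(self):
        ds = _records([(f"R{i}", f"Genus sp{i}", "Rodentia") for i in range(100)])
        from barcodeqc.qc import QCFlag

        flags = [QCFlag(accession="R1", species="Genus sp1", flag_type="deep_intra",
                        evidence={"intra_min": 0.1, "intra_max": 0.1}),
                 QCFlag(accession="R2", species="Genus sp2", flag_type="paradox",
                        evidence={"intra_min": 0.1, "intra_max": 0.1,
                                  "inter_min": 0.01, "inter_max": 0.01})]
        ratios = error_ratio_by_group(flags, ds)
        assert ratios.loc[ratios.group == "Rodentia", "error_ratio_pct"].item() == 2.0

    def test_no_flags_all_zero(self, sim_clean):
        ds, _, _ = sim_clean
        ratios = error_ratio_by_group([], ds)
        assert (ratios.error_ratio_pct == 0).all()

    def test_injected_relabels_recovered_within_binomial_error(self):
        """With 5% relabels injected, the paradox-flag ratio over all groups
        should sit inside the exact binomial interval for the draw."""
        from scipy import stats

        from barcodeqc.simulate import ErrorSpec, SimConfig, simulate_dataset

        cfg = SimConfig(seed=3, errors=ErrorSpec(relabel=0.05))
        ds, truth, _ = simulate_dataset(cfg)
        dm = distance_matrix(ds)
        report = flag_potential_errors(dm, ds)
        flags = [f for f in report.flags if f.flag_type == "paradox"]
        ratios = error_ratio_by_group(flags, ds)
        overall = ratios.n_flagged.sum() / ratios.n_records.sum()
        lo, hi = stats.binom.interval(0.999, len(ds), 0.05)
        assert lo / len(ds) <= overall <= hi / len(ds)
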