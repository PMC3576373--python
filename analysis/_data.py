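"""Shared access to the study dataset for the numbered analysis scripts.

The alignment is bulky, so it lives under scratch/; when absent it is
regenerated deterministically from the study conditions (seed 0, 5%
relabels + 2% contaminations), so every script can run standalone.
"""

from pathlib import Path

import pandas as pd

from barcodeqc.alignment import AlignedDataset, read_aligned_fasta, write_aligned_fasta
from barcodeqc.simulate import ErrorSpec, SimConfig, simulate_dataset, write_truth_table

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
TRUTH_DIR = ROOT / "results" / "synthetic"

STUDY_CONFIG = SimConfig(seed=0, errors=ErrorSpec(relabel=0.05, contaminate=0.02))


def build_dataset() -> tuple[AlignedDataset, pd.DataFrame]:
    """(Re)generate the study dataset and persist it."""
    SCRATCH.mkdir(exist_ok=True)
    TRUTH_DIR.mkdir(parents=True, exist_ok=True)
    ds, truth, tree = simulate_dataset(STUDY_CONFIG)
    write_aligned_fasta(ds, SCRATCH / "alignment.fasta")
    write_truth_table(truth, TRUTH_DIR / "truth.tsv")
    (TRUTH_DIR / "species_tree.nwk").write_text(tree.newick() + "\n")
    return ds, truth


def load_dataset() -> tuple[AlignedDataset, pd.DataFrame]:
    """Load the study dataset, regenerating it if not on disk."""
    fasta = SCRATCH / "alignment.fasta"
    truth = TRUTH_DIR / "truth.tsv"
    if fasta.exists() and truth.exists():
        return read_aligned_fasta(fasta), pd.read_csv(truth, sep="\t")
    return build_dataset()
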