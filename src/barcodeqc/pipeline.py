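"""End-to-end QC run: read -> trim -> distances -> partition -> flags ->
tree -> saturation -> report bundle.

Every artifact carries the thresholds used in a comment header, and the run
manifest (package version, config echo, seed) suffices to reproduce the run
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .alignment import (AlignedDataset, DEFAULT_HEADER_PATTERN, drop_length_outliers,
                        read_aligned_fasta, trim_flanks)
from .distances import DEFAULT_MIN_OVERLAP, distance_matrix, prune_undefined
from .njtree import bootstrap_support, neighbor_joining
from .qc import FlagConfig, error_ratio_by_group, flag_potential_errors, partition_divergences
from .saturation import PARTITIONS, saturation_frame, saturation_points

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One QC run: input, filters, thresholds, outputs."""

    input: str  #: aligned FASTA (plain or gzip)
    outdir: str
    header_pattern: str = DEFAULT_HEADER_PATTERN
    frame_offset: int = 0
    trim_window: tuple[int, int] | None = None  #: 0-based half-open columns
    min_defined_sites: int | None = None  #: drop shorter records when set
    min_overlap: int = DEFAULT_MIN_OVERLAP
    flags: FlagConfig = field(default_factory=FlagConfig)
    bootstrap_reps: int = 0  #: 0 = plain NJ tree without supports
    partitions: tuple[str, ...] = PARTITIONS
    bin_width: float = 0.01
    seed: int = 0


def parse_config_file(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file into RunConfig keywords.

    Lines starting with ``#`` are comments.  Recognised keys mirror the
    RunConfig fields; ``t_deep``/``t_shallow``/``t_identical`` populate the
    flag thresholds and ``trim_start``/``trim_end`` the trim window.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    out: dict = {}
    int_keys = {"frame_offset", "min_defined_sites", "min_overlap",
                "bootstrap_reps", "seed"}
    float_keys = {"bin_width"}
    flag_keys = {"t_deep", "t_shallow", "t_identical"}
    flags: dict[str, float] = {}
    for key, value in raw.items():
        if key in int_keys:
            out[key] = int(value)
        elif key in float_keys:
            out[key] = float(value)
        elif key in flag_keys:
            flags[key] = float(value)
        elif key in ("trim_start", "trim_end"):
            pass
        elif key in ("input", "outdir", "header_pattern"):
            out[key] = value
        elif key == "partitions":
            out[key] = tuple(value.split())
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    if "trim_start" in raw or "trim_end" in raw:
        out["trim_window"] = (int(raw["trim_start"]), int(raw["trim_end"]))
    if flags:
        out["flags"] = FlagConfig(**flags)
    return out


def _header(cfg: RunConfig) -> str:
    return (f"# barcodeqc {__version__} seed={cfg.seed} min_overlap={cfg.min_overlap} "
            f"t_deep={cfg.flags.t_deep} t_shallow={cfg.flags.t_shallow}\n")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full QC workflow; returns the artifact paths.

    Artifacts: distance matrix (PHYLIP + long-format pairs), Newick tree,
    saturation tables, divergence histograms, flag report (TSV + Markdown),
    per-group error ratios, and a JSON run manifest.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    stage("read")
    ds = read_aligned_fasta(cfg.input, header_pattern=cfg.header_pattern,
                            frame_offset=cfg.frame_offset,
                            skip_report=out / "skipped_records.tsv")
    if cfg.trim_window is not None:
        stage("trim")
        ds = trim_flanks(ds, *cfg.trim_window)
    if cfg.min_defined_sites is not None:
        stage("length-filter")
        ds, removed = drop_length_outliers(ds, cfg.min_defined_sites)
        (out / "removed_records.tsv").write_text(
            "accession\tdefined_sites\n" +
            "".join(f"{a}\t{c}\n" for a, c in removed))

    stage("distances")
    dm = distance_matrix(ds, min_overlap=cfg.min_overlap)
    dm.to_phylip(out / "distances.phylip")
    with open(out / "distance_pairs.tsv", "w") as fh:
        fh.write(_header(cfg))
        dm.to_pairs_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")
    artifacts["distances"] = out / "distances.phylip"
    artifacts["distance_pairs"] = out / "distance_pairs.tsv"

    stage("partition")
    part = partition_divergences(dm, ds, bin_width=cfg.bin_width)
    with open(out / "divergence_histograms.tsv", "w") as fh:
        fh.write(_header(cfg))
        part.histogram().to_csv(fh, sep="\t", index=False, float_format="%.8g")
    artifacts["histograms"] = out / "divergence_histograms.tsv"

    stage("flags")
    report = flag_potential_errors(dm, ds, cfg.flags)
    report.write_tsv(out / "flag_report.tsv")
    report.write_markdown(out / "flag_report.md")
    artifacts["flag_report"] = out / "flag_report.tsv"
    ratios = error_ratio_by_group(report.flags, ds)
    with open(out / "error_ratios.tsv", "w") as fh:
        fh.write(_header(cfg))
        ratios.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    artifacts["error_ratios"] = out / "error_ratios.tsv"

    stage("tree")
    complete, dropped = prune_undefined(dm)
    if len(complete.labels) >= 2:
        if cfg.bootstrap_reps > 0:
            keep = set(complete.labels)
            sub = ds.replace_records([r for r in ds if r.accession in keep])
            boot = bootstrap_support(sub, reps=cfg.bootstrap_reps, seed=cfg.seed,
                                     min_overlap=cfg.min_overlap)
            tree = boot.tree
        else:
            tree = neighbor_joining(complete)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        artifacts["tree"] = out / "tree.nwk"

    stage("saturation")
    sat_paths = []
    for partition in cfg.partitions:
        points, omitted = saturation_points(ds, partition, min_overlap=max(1, cfg.min_overlap // 3))
        p = out / f"saturation_{partition}.tsv"
        with open(p, "w") as fh:
            fh.write(_header(cfg))
            fh.write(f"# omitted_pairs={omitted}\n")
            saturation_frame(points).to_csv(fh, sep="\t", index=False, float_format="%.8g")
        sat_paths.append(str(p))
    artifacts["saturation"] = out / f"saturation_{cfg.partitions[0]}.tsv"

    manifest = {
        "package": "barcodeqc",
        "version": __version__,
        "seed": cfg.seed,
        "config": {**asdict(cfg), "flags": asdict(cfg.flags)},
        "n_records": len(ds),
        "alignment_length": ds.length,
        "n_flags": len(report.flags),
        "pruned_for_tree": dropped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = out / "manifest.json"
    return artifacts
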