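"""Substitution-saturation curves.

Plots (or tabulates) the observed number of transitions and transversions
per sequence pair against the pair's K2P divergence, for all positions,
first+second codon positions, and third positions separately.  Saturation
shows up as a plateau in the transition counts at high divergence while
transversions keep accumulating — repeated hits at the same site overwrite
earlier transitions.

The x-axis uses the K2P distance computed on the same position partition,
and plateau detection is descriptive: the regression slope of transition
counts against divergence inside a high-divergence window is compared with
the slope inside a low-divergence window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .alignment import AlignedDataset
from .distances import _pairwise_arrays

Partition = Literal["all", "pos12", "pos3"]
PARTITIONS: tuple[Partition, ...] = ("all", "pos12", "pos3")


@dataclass(frozen=True)
class SaturationPoint:
    """One pair on the saturation scatter: counts and divergence."""

    acc_a: str
    acc_b: str
    s: int  #: transition count
    v: int  #: transversion count
    d: float  #: K2P divergence on the selected positions
    partition: Partition


def codon_partition(ds: AlignedDataset, partition: Partition) -> AlignedDataset:
    """Restrict an alignment to a codon-position class.

    ``pos3`` keeps third positions, ``pos12`` first and second, ``all`` is
    the identity.  Positions are taken relative to ``ds.frame_offset``.
    """
    if partition == "all":
        return ds
    if ds.length < 3:
        raise ValueError("alignment shorter than one codon cannot be partitioned")
    cols = np.arange(ds.length)
    pos = (cols - ds.frame_offset) % 3  # 0,1 = first/second, 2 = third
    keep = cols[pos == 2] if partition == "pos3" else cols[pos != 2]
    records = [
        replace(r, seq=np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8)[keep].tobytes().decode("ascii"))
        for r in ds
    ]
    return AlignedDataset(records, frame_offset=0)


def saturation_points(
    ds: AlignedDataset,
    partition: Partition = "all",
    min_overlap: int = 1,
) -> tuple[list[SaturationPoint], int]:
    """One point per unordered pair with a defined distance on ``partition``.

    Returns the points and the number of pairs omitted because their
    distance was undefined (saturated or too little overlap).
    """
    if len(ds) < 2:
        raise ValueError("need at least two records")
    sub = codon_partition(ds, partition)
    d, ok, ts, tv, _ = _pairwise_arrays(sub.codes, min_overlap)
    labels = ds.accessions
    points: list[SaturationPoint] = []
    omitted = 0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if ok[i, j]:
                points.append(
                    SaturationPoint(labels[i], labels[j], int(ts[i, j]), int(tv[i, j]),
                                    float(d[i, j]), partition)
                )
            else:
                omitted += 1
    return points, omitted


def saturation_frame(points: Iterable[SaturationPoint]) -> pd.DataFrame:
    """Long-format table: acc_a, acc_b, partition, s, v, d."""
    return pd.DataFrame(
        [
            {"acc_a": p.acc_a, "acc_b": p.acc_b, "partition": p.partition,
             "s": p.s, "v": p.v, "d": p.d}
            for p in points
        ],
        columns=["acc_a", "acc_b", "partition", "s", "v", "d"],
    )


def windowed_slope(points: Iterable[SaturationPoint], lo: float, hi: float,
                   count: Literal["s", "v"] = "s") -> float:
    """Least-squares slope of a substitution count vs divergence in a window.

    Descriptive plateau check: the transition slope over a high-divergence
    window falling below the slope near the origin indicates saturation.
    """
    pts = [p for p in points if lo <= p.d <= hi]
    if len(pts) < 3:
        raise ValueError(f"fewer than 3 points with d in [{lo}, {hi}]")
    x = np.array([p.d for p in pts])
    y = np.array([getattr(p, count) for p in pts], dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def plot_saturation(points: Iterable[SaturationPoint], path: str | Path,
                    title: str | None = None) -> None:
    """Scatter of transitions (s) and transversions (v) against divergence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = list(points)
    d = [p.d for p in pts]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(d, [p.s for p in pts], s=8, marker="x", label="transitions (s)")
    ax.scatter(d, [p.v for p in pts], s=8, marker="^", facecolors="none",
               edgecolors="tab:orange", label="transversions (v)")
    ax.set_xlabel("K2P divergence")
    ax.set_ylabel("substitutions per pair")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
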