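"""Kimura 2-parameter pairwise distances with pairwise deletion.

For each unordered sequence pair, sites where either member carries a gap,
``N`` or an IUPAC ambiguity code are excluded (pairwise deletion).  The
remaining sites are classified identical / transition (A<->G, C<->T) /
transversion, giving the transition proportion P and transversion
proportion Q.  The K2P distance is

    d = -1/2 * ln[ (1 - 2P - Q) * sqrt(1 - 2Q) ]

which is undefined (saturated) when either logarithm argument is
non-positive.  Undefined entries are carried as an explicit mask, never as a
sentinel number: downstream consumers must handle them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignedDataset, encode

logger = logging.getLogger(__name__)

#: minimum number of shared defined sites for a distance to be trusted;
#: below this the K2P estimate is too variable to drive QC flags
DEFAULT_MIN_OVERLAP = 300


@dataclass(frozen=True)
class PairStats:
    """Per-pair substitution summary over the shared defined sites."""

    ts: int  #: transition count
    tv: int  #: transversion count
    n_sites: int  #: compared (shared defined) sites

    @property
    def P(self) -> float:
        """Transition proportion; 0.0 for an empty comparison."""
        return self.ts / self.n_sites if self.n_sites else 0.0

    @property
    def Q(self) -> float:
        """Transversion proportion; 0.0 for an empty comparison."""
        return self.tv / self.n_sites if self.n_sites else 0.0


def pair_site_counts(a: str | np.ndarray, b: str | np.ndarray) -> PairStats:
    """Classify shared defined sites of two equal-length aligned sequences.

    Accepts raw strings or pre-encoded uint8 code arrays.
    """
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise ValueError("sequences must have equal aligned length")
    valid = (ca < 4) & (cb < 4)
    diff = valid & (ca != cb)
    # codes: A=0, C=1, G=2, T=3 -- transitions connect codes of equal parity
    ts = diff & ((ca & 1) == (cb & 1))
    return PairStats(ts=int(ts.sum()), tv=int(diff.sum() - ts.sum()), n_sites=int(valid.sum()))


def k2p(stats: PairStats) -> float | None:
    """K2P distance for a pair summary, or ``None`` when undefined.

    Undefined means the comparison is empty (``n_sites == 0``) or the
    observed proportions are outside the model's domain (saturation).
    """
    if stats.n_sites == 0:
        return None
    return k2p_from_proportions(stats.P, stats.Q)


def k2p_from_proportions(P: float, Q: float) -> float | None:
    """Evaluate the K2P closed form; ``None`` outside its domain."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with an undefined-entry mask.

    ``d`` holds NaN wherever ``defined`` is False; consumers must check the
    mask rather than the NaNs.  ``ts``, ``tv`` and ``n_sites`` keep the
    underlying pair summaries so long-format export can report P and Q.
    """

    labels: list[str]
    d: np.ndarray
    defined: np.ndarray
    ts: np.ndarray
    tv: np.ndarray
    n_sites: np.ndarray
    min_overlap_used: int

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float | None:
        """Distance between two accessions, or ``None`` when undefined."""
        i, j = self._index[a], self._index[b]
        return float(self.d[i, j]) if self.defined[i, j] else None

    def submatrix(self, idx: list[int]) -> "DistanceMatrix":
        ix = np.asarray(idx)
        return DistanceMatrix(
            labels=[self.labels[i] for i in idx],
            d=self.d[np.ix_(ix, ix)],
            defined=self.defined[np.ix_(ix, ix)],
            ts=self.ts[np.ix_(ix, ix)],
            tv=self.tv[np.ix_(ix, ix)],
            n_sites=self.n_sites[np.ix_(ix, ix)],
            min_overlap_used=self.min_overlap_used,
        )

    def to_pairs_frame(self) -> pd.DataFrame:
        """Long-format table: acc_a, acc_b, P, Q, n_sites, d (NaN = undefined)."""
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                ns = int(self.n_sites[i, j])
                rows.append(
                    {
                        "acc_a": self.labels[i],
                        "acc_b": self.labels[j],
                        "P": self.ts[i, j] / ns if ns else 0.0,
                        "Q": self.tv[i, j] / ns if ns else 0.0,
                        "n_sites": ns,
                        "d": self.d[i, j] if self.defined[i, j] else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def to_phylip(self, path: str | Path) -> None:
        """Write as a square PHYLIP matrix (undefined entries as -1.0)."""
        with open(path, "w") as out:
            out.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                vals = np.where(self.defined[i], self.d[i], -1.0)
                out.write(lab + "  " + " ".join(f"{v:.8f}" for v in vals) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (negative entries = undefined).

    Pair summaries (P, Q, site counts) are not recoverable from the format
    and are zero-filled.
    """
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels: list[str] = []
        rows = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(labels) != n or any(len(r) != n for r in rows):
        raise ValueError(f"malformed PHYLIP matrix in {path}")
    d = np.array(rows)
    defined = d >= 0.0
    d = np.where(defined, d, np.nan)
    zeros = np.zeros((n, n), dtype=np.int64)
    return DistanceMatrix(labels=labels, d=d, defined=defined,
                          ts=zeros, tv=zeros.copy(), n_sites=zeros.copy(),
                          min_overlap_used=0)


def _pairwise_arrays(codes: np.ndarray, min_overlap: int):
    """Vectorised all-pairs site classification over an encoded alignment."""
    n = codes.shape[0]
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    n_sites = np.zeros((n, n), dtype=np.int64)
    valid = codes < 4
    parity = codes & 1
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = v & (codes[i] != codes[i + 1 :])
        is_ts = diff & (parity[i] == parity[i + 1 :])
        ts_row = is_ts.sum(axis=1)
        diff_row = diff.sum(axis=1)
        ts[i, i + 1 :] = ts_row
        tv[i, i + 1 :] = diff_row - ts_row
        n_sites[i, i + 1 :] = v.sum(axis=1)
    ts += ts.T
    tv += tv.T
    n_sites += n_sites.T
    np.fill_diagonal(n_sites, codes.shape[1])

    with np.errstate(divide="ignore", invalid="ignore"):
        ns = n_sites.astype(float)
        P = np.divide(ts, ns, out=np.zeros_like(ns), where=ns > 0)
        Q = np.divide(tv, ns, out=np.zeros_like(ns), where=ns > 0)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        ok = (w1 > 0) & (w2 > 0) & (n_sites >= min_overlap)
        d = np.where(ok, -0.5 * np.log(np.where(ok, w1 * np.sqrt(np.abs(w2)), 1.0)), np.nan)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(ok, True)
    return d, ok, ts, tv, n_sites


def distance_matrix(ds: AlignedDataset, min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion.

    Entries whose shared defined-site count falls below ``min_overlap``, or
    whose observed proportions saturate the model, are marked undefined.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(ds) == 1:
        logger.warning("distance matrix requested for a single record")
    d, ok, ts, tv, n_sites = _pairwise_arrays(ds.codes, min_overlap)
    return DistanceMatrix(
        labels=ds.accessions, d=d, defined=ok, ts=ts, tv=tv, n_sites=n_sites,
        min_overlap_used=min_overlap,
    )


def prune_undefined(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Drop the fewest records needed to make every entry defined.

    Greedy by undefined-degree: repeatedly remove the label with the most
    undefined partners (lowest index on ties).  Returns the complete
    submatrix and the dropped labels.
    """
    keep = list(range(len(dm.labels)))
    dropped: list[str] = []
    while True:
        sub = dm.defined[np.ix_(keep, keep)]
        bad = (~sub).sum(axis=1)
        if bad.max(initial=0) == 0:
            break
        worst = int(np.argmax(bad))
        dropped.append(dm.labels[keep[worst]])
        del keep[worst]
    if dropped:
        logger.info("pruned %d records with undefined distances: %s", len(dropped), dropped)
    return dm.submatrix(keep), dropped
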