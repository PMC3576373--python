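"""Species-labelled aligned sequence sets.

The unit of analysis is one accession: an identifier, a binomial species
label, an optional higher-taxon group label, and an aligned nucleotide
string.  A dataset is a rectangular alignment of such records together with
the reading-frame offset of its first column (needed for codon-position
partitioning downstream).

Sequences are upper-cased on read and ``U`` is mapped to ``T``.  Only the
four canonical bases take part in any distance computation; gaps, ``N`` and
IUPAC ambiguity codes are treated as undefined sites and excluded pairwise.
Coordinates are 0-based with half-open windows throughout the package.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: canonical base -> code; everything else is UNDEFINED_CODE
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

UNDEFINED_CODE = np.uint8(255)

DEFAULT_HEADER_PATTERN = "accession binomial group?"


class RaggedAlignmentError(ValueError):
    """Raised when sequences in one dataset differ in length."""


class HeaderParseError(ValueError):
    """Raised when a FASTA header cannot be parsed into accession/species."""


@dataclass(frozen=True)
class SeqRecord:
    """One accession of an aligned dataset.

    Parameters
    ----------
    accession : unique identifier (e.g. a GenBank accession).
    species : binomial (or trinomial) species label, space separated.
    seq : aligned nucleotide string, upper case, ``U`` already mapped to ``T``.
    group : optional higher-taxon label (order, family, ...).
    """

    accession: str
    species: str
    seq: str
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.species:
            raise ValueError(f"record {self.accession!r}: species must be non-empty")

    @property
    def species_key(self) -> str:
        """Species-rank grouping key: genus + epithet, subspecies dropped."""
        return " ".join(self.species.split()[:2])

    def defined_sites(self) -> int:
        """Number of canonical A/C/G/T sites (gaps, N, ambiguities excluded)."""
        return int((encode(self.seq) != UNDEFINED_CODE).sum())


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0, C=1, G=2, T=3, else 255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray, undefined: str = "-") -> str:
    out = np.full(codes.shape, ord(undefined), dtype=np.uint8)
    valid = codes < 4
    out[valid] = _DECODE[codes[valid]]
    return out.tobytes().decode("ascii")


class AlignedDataset:
    """A rectangular alignment of :class:`SeqRecord` with a known frame offset.

    ``frame_offset`` is the column index (0, 1 or 2) of the first codon
    position; it is re-derived automatically when the alignment is trimmed.
    """

    def __init__(self, records: Sequence[SeqRecord], frame_offset: int = 0):
        records = tuple(records)
        if not records:
            raise ValueError("dataset must contain at least one record")
        if not 0 <= frame_offset < 3:
            raise ValueError("frame_offset must be 0, 1 or 2")
        length = len(records[0].seq)
        for rec in records:
            if len(rec.seq) != length:
                short = min(records, key=lambda r: len(r.seq))
                raise RaggedAlignmentError(
                    f"alignment is ragged: record {short.accession!r} has length "
                    f"{len(short.seq)}, expected {max(len(r.seq) for r in records)}"
                )
        seen: set[str] = set()
        for rec in records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)
        self.records = records
        self.frame_offset = frame_offset

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SeqRecord:
        return self.records[i]

    @property
    def length(self) -> int:
        """Alignment length in columns."""
        return len(self.records[0].seq)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    @property
    def species(self) -> list[str]:
        """Species-rank label per record (subspecies epithets dropped)."""
        return [r.species_key for r in self.records]

    @cached_property
    def codes(self) -> np.ndarray:
        """(n_records, length) uint8 matrix; 255 marks undefined sites."""
        return np.vstack([encode(r.seq) for r in self.records])

    def replace_records(self, records: Sequence[SeqRecord], frame_offset: int | None = None) -> "AlignedDataset":
        return AlignedDataset(records, self.frame_offset if frame_offset is None else frame_offset)


def parse_header(header: str, pattern: str = DEFAULT_HEADER_PATTERN) -> tuple[str, str, str | None]:
    """Parse a FASTA defline into (accession, species, group).

    ``pattern`` is a whitespace-separated field template over
    ``{accession, binomial, species, group}``; a trailing ``?`` marks the
    field optional.  ``binomial`` consumes either one underscore-joined token
    (``Genus_species``) or, failing that, two consecutive tokens
    (``Genus species``); ``species`` always consumes a single token.
    Underscores inside species names are normalised to spaces.
    """
    tokens = header.split()
    fields = pattern.split()
    out: dict[str, str | None] = {"accession": None, "species": None, "group": None}
    pos = 0
    for field in fields:
        optional = field.endswith("?")
        name = field.rstrip("?")
        if pos >= len(tokens):
            if optional:
                continue
            raise HeaderParseError(f"header {header!r}: missing field {name!r}")
        tok = tokens[pos]
        if name == "binomial":
            if "_" in tok:
                out["species"] = tok.replace("_", " ")
                pos += 1
            elif pos + 1 < len(tokens):
                out["species"] = f"{tok} {tokens[pos + 1]}"
                pos += 2
            elif optional:
                continue
            else:
                raise HeaderParseError(f"header {header!r}: no binomial species name")
        elif name == "species":
            out["species"] = tok.replace("_", " ")
            pos += 1
        else:
            out[name] = tok
            pos += 1
    if not out["accession"] or not out["species"]:
        raise HeaderParseError(f"header {header!r}: accession/species not found")
    return out["accession"], out["species"], out["group"]


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_aligned_fasta(
    path: str | Path,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    frame_offset: int = 0,
    skip_report: str | Path | None = None,
) -> AlignedDataset:
    """Read an aligned FASTA (plain or gzip) into an :class:`AlignedDataset`.

    Records whose headers cannot be parsed are skipped, logged, and — when
    ``skip_report`` is given — listed in a tab-separated report
    (accession-or-header, reason).  A ragged alignment or an empty file is a
    hard error.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    skipped: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for entry in SeqIO.parse(fh, "fasta"):
            header = entry.description
            seq = str(entry.seq).upper().replace("U", "T")
            try:
                accession, species, group = parse_header(header, header_pattern)
            except HeaderParseError as exc:
                skipped.append((header, str(exc)))
                logger.warning("skipping unparseable header: %s", exc)
                continue
            records.append(SeqRecord(accession, species, seq, group))
    if skip_report is not None:
        with open(skip_report, "w") as out:
            out.write("header\treason\n")
            for header, reason in skipped:
                out.write(f"{header}\t{reason}\n")
    if not records:
        raise ValueError(f"no usable records in {path}")
    return AlignedDataset(records, frame_offset=frame_offset)


def write_aligned_fasta(ds: AlignedDataset, path: str | Path) -> None:
    """Write as FASTA with ``accession Genus_species [group]`` headers."""
    with _open_text(Path(path), "wt") as out:
        for rec in ds:
            header = f"{rec.accession} {rec.species.replace(' ', '_')}"
            if rec.group:
                header += f" {rec.group}"
            out.write(f">{header}\n{rec.seq}\n")


def trim_flanks(ds: AlignedDataset, window_start: int, window_end: int) -> AlignedDataset:
    """Restrict the alignment to columns ``[window_start, window_end)``.

    The frame offset is recomputed relative to the new first column, so codon
    partitioning stays correct after trimming.
    """
    if not (0 <= window_start < window_end <= ds.length):
        raise ValueError(
            f"invalid window [{window_start}, {window_end}) for alignment of length {ds.length}"
        )
    new_offset = (ds.frame_offset - window_start) % 3
    records = [replace(r, seq=r.seq[window_start:window_end]) for r in ds]
    return AlignedDataset(records, frame_offset=new_offset)


def drop_length_outliers(
    ds: AlignedDataset, min_defined_sites: int
) -> tuple[AlignedDataset, list[tuple[str, int]]]:
    """Remove records with fewer than ``min_defined_sites`` canonical bases.

    Returns the filtered dataset and a removal report of
    ``(accession, defined_site_count)`` pairs.  Removing every record is a
    hard error (the threshold is too strict for the data).
    """
    if min_defined_sites < 1:
        raise ValueError("min_defined_sites must be >= 1")
    counts = (ds.codes != UNDEFINED_CODE).sum(axis=1)
    keep = [rec for rec, c in zip(ds, counts) if c >= min_defined_sites]
    removed = [(rec.accession, int(c)) for rec, c in zip(ds, counts) if c < min_defined_sites]
    if not keep:
        raise ValueError(
            f"min_defined_sites={min_defined_sites} removed every record; lower the threshold"
        )
    if removed:
        logger.info("dropped %d short records", len(removed))
    return ds.replace_records(keep), removed
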