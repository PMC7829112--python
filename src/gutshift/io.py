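"""Readers and writers for ASV tables, taxonomies, metadata and alignments.

All tabular formats are plain TSV (UTF-8, tab-separated, no quoting);
lines starting with ``#`` are treated as comments and skipped.  ASV
tables are oriented ASVs x samples — rows are ASVs, columns are samples
— and transposed input is never auto-detected: a table that violates the
declared orientation fails loudly downstream rather than being silently
flipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union

import numpy as np

PathLike = Union[str, Path]

#: Residues accepted in alignments: the four bases, U (normalized to T on
#: read), gap, and the IUPAC ambiguity codes.
IUPAC_CHARS = frozenset("ACGTU-NRYSWKMBDHV")

#: Characters other than A/C/G/T, i.e. gaps, N and ambiguity codes.
NON_ACGT = frozenset("-NRYSWKMBDHV")

TaxonomyTable = Dict[str, List[str]]
SampleMetadata = Dict[str, str]

_ASV_ID_RE = re.compile(r"^\S+$")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class AsvTable:
    """An ASV count table: non-negative integer counts, ASVs x samples."""

    asv_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.asv_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.asv_ids)} ASVs x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        for axis_name, ids in (("ASV", self.asv_ids), ("sample", self.sample_ids)):
            seen = set()
            for x in ids:
                if x in seen:
                    raise ValueError(f"duplicate {axis_name} id: {x!r}")
                seen.add(x)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_depths(self) -> np.ndarray:
        """Per-sample read totals (column sums)."""
        return self.counts.sum(axis=0)

    def subset(self, asv_ids=None, sample_ids=None) -> "AsvTable":
        """Return a sub-table restricted to the given ids (order preserved)."""
        rows = (
            [self.asv_ids.index(a) for a in asv_ids]
            if asv_ids is not None
            else list(range(self.n_asvs))
        )
        cols = (
            [self.sample_ids.index(s) for s in sample_ids]
            if sample_ids is not None
            else list(range(self.n_samples))
        )
        return AsvTable(
            [self.asv_ids[i] for i in rows],
            [self.sample_ids[j] for j in cols],
            self.counts[np.ix_(rows, cols)] if rows and cols else
            np.zeros((len(rows), len(cols)), dtype=np.int64),
        )


@dataclass
class Alignment:
    """A multiple sequence alignment of equal-length nucleotide strings.

    Sequences are stored uppercase with U normalized to T; characters are
    restricted to the IUPAC nucleotide set plus the gap symbol.
    """

    seq_ids: List[str]
    sequences: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.seq_ids) != len(self.sequences):
            raise ValueError("seq_ids and sequences differ in length")
        seen = set()
        for sid in self.seq_ids:
            if sid in seen:
                raise ValueError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
        norm = []
        length = None
        for sid, seq in zip(self.seq_ids, self.sequences):
            s = seq.upper().replace("U", "T").replace(".", "-")
            if length is None:
                length = len(s)
            elif len(s) != length:
                raise ValueError(
                    f"sequence {sid!r} has length {len(s)}, expected {length}"
                )
            for pos, ch in enumerate(s):
                if ch not in IUPAC_CHARS and ch != "-":
                    raise ValueError(
                        f"sequence {sid!r}: invalid character {ch!r} "
                        f"at position {pos}"
                    )
            norm.append(s)
        self.sequences = norm

    @property
    def n_seqs(self) -> int:
        return len(self.seq_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_matrix(self) -> np.ndarray:
        """Character matrix, shape (n_seqs, length), dtype '<U1'."""
        return np.array([list(s) for s in self.sequences])


def _data_lines(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_asv_table(path: PathLike) -> AsvTable:
    """Read an ASVs x samples count table from TSV.

    The header row carries sample ids (first cell is a label for the ASV
    id column and is ignored); each subsequent row is an ASV id followed
    by integer counts.
    """
    lines = _data_lines(path)
    try:
        _, header = next(lines)
    except StopIteration:
        raise ParseError(f"{path}: empty file") from None
    cells = header.split("\t")
    if len(cells) < 1 or not cells[0]:
        raise ParseError(f"{path}: malformed header row")
    sample_ids = cells[1:]
    asv_ids: List[str] = []
    rows: List[List[int]] = []
    for lineno, line in lines:
        cells = line.split("\t")
        if len(cells) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                f"got {len(cells)}"
            )
        asv_id = cells[0]
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {cell!r} for ASV "
                    f"{asv_id!r}, sample {sample_ids[j]!r}"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}:{lineno}: negative count for ASV {asv_id!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            row.append(value)
        asv_ids.append(asv_id)
        rows.append(row)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(sample_ids)), dtype=np.int64)
    )
    try:
        return AsvTable(asv_ids, sample_ids, counts)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_asv_table(table: AsvTable, path: PathLike) -> None:
    """Write an :class:`AsvTable` as TSV; inverted exactly by :func:`read_asv_table`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("asv_id\t" + "\t".join(table.sample_ids) + "\n")
        for i, asv_id in enumerate(table.asv_ids):
            fh.write(asv_id + "\t" + "\t".join(map(str, table.counts[i])) + "\n")


def read_taxonomy(path: PathLike) -> TaxonomyTable:
    """Read a two-column TSV mapping ASV id -> semicolon-joined lineage.

    Lineage ranks are free strings ordered domain..genus (at most 7);
    surrounding whitespace per rank is stripped and empty ranks retained.
    """
    taxonomy: TaxonomyTable = {}
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        asv_id, lineage_str = cells[0], cells[1]
        if asv_id == "asv_id" and not taxonomy:
            continue  # optional header row
        if not _ASV_ID_RE.match(asv_id):
            raise ParseError(f"{path}:{lineno}: invalid ASV id {asv_id!r}")
        if asv_id in taxonomy:
            raise ParseError(f"{path}:{lineno}: duplicate ASV id {asv_id!r}")
        lineage = [rank.strip() for rank in lineage_str.split(";")]
        if len(lineage) > 7:
            raise ParseError(
                f"{path}:{lineno}: lineage for {asv_id!r} has "
                f"{len(lineage)} ranks (max 7)"
            )
        taxonomy[asv_id] = lineage
    return taxonomy


def write_taxonomy(taxonomy: TaxonomyTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("asv_id\tlineage\n")
        for asv_id, lineage in taxonomy.items():
            fh.write(f"{asv_id}\t{';'.join(lineage)}\n")


def read_metadata(path: PathLike) -> SampleMetadata:
    """Read a two-column TSV mapping sample id -> group label."""
    metadata: SampleMetadata = {}
    for lineno, line in _data_lines(path):
        cells = line.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        sample_id, group = cells[0], cells[1].strip()
        if sample_id == "sample_id" and not metadata:
            continue  # optional header row
        if not group:
            raise ParseError(f"{path}:{lineno}: empty group for {sample_id!r}")
        if sample_id in metadata:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sample_id!r}")
        metadata[sample_id] = group
    return metadata


def write_metadata(metadata: SampleMetadata, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample_id, group in metadata.items():
            fh.write(f"{sample_id}\t{group}\n")


def read_fasta(path: PathLike) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises on ragged sequence lengths or characters outside the IUPAC
    nucleotide set (the offending sequence and position are named).
    """
    import skbio.io as skio

    seq_ids: List[str] = []
    sequences: List[str] = []
    for seq in skio.read(str(path), format="fasta", verify=False):
        seq_ids.append(seq.metadata["id"])
        sequences.append(str(seq))
    try:
        return Alignment(seq_ids, sequences)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_fasta(alignment: Alignment, path: PathLike, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in zip(alignment.seq_ids, alignment.sequences):
            fh.write(f">{sid}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")
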