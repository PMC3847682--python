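"""Readers/writers for the on-disk formats shared by the toolkit.

All internal coordinates are 0-based half-open; everything serialized to
disk uses 1-based inclusive coordinates (the convention of tabular
alignment output).  The two converters below are exact inverses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger("polygenespace")

NT_ALPHABET = set("ACGTN")


@dataclass
class SequenceRecord:
    """A named sequence, nucleotide or amino acid, with optional Phred quals."""

    id: str
    seq: str
    qual: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"quality length {len(self.qual)} != sequence length "
                f"{len(self.seq)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MarkerRecord:
    """A genetically mapped marker: map position in centiMorgan plus its sequence."""

    marker_id: str
    chromosome: str
    cm_position: float
    seq: str

    def __post_init__(self) -> None:
        if not (self.cm_position >= 0 and self.cm_position == self.cm_position):
            raise ValueError(f"cM position of {self.marker_id!r} must be finite and >= 0")


@dataclass
class HitTableRow:
    """One row of the 12-column tabular alignment format.

    Coordinates are stored 0-based half-open in memory and written 1-based
    inclusive.  ``frame`` is 0 for protein-protein comparisons, otherwise
    in {-3..-1, 1..3}.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len_aa: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int = 0
    score: float = 0.0
    mismatches: int = 0
    gap_opens: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.aln_len_aa <= 0:
            raise ValueError("aln_len_aa must be positive")


def to_disk_coord(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_disk_coord(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, order preserved).

    Raises ``ValueError`` on duplicate ids; warns on an empty file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"no sequences found in {path}")
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a Sanger (Phred+33) FASTQ file."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                rec.id,
                str(rec.seq).upper(),
                list(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [30] * len(rec.seq)
            qstring = "".join(chr(min(q, 93) + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstring}\n")


def read_marker_map(path: str | Path) -> list[MarkerRecord]:
    """Read a 4-column TSV marker map (header row) sorted by (chromosome, cM).

    The sort is stable, so markers sharing a cM position keep file order.
    """
    markers: list[MarkerRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            return []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}")
            marker_id, chromosome, cm, seq = fields
            try:
                cm_val = float(cm)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric cM position {cm!r}") from None
            markers.append(MarkerRecord(marker_id, chromosome, cm_val, seq.upper()))
    markers.sort(key=lambda m: (m.chromosome, m.cm_position))
    return markers


def write_marker_map(markers: Iterable[MarkerRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchromosome\tcm_position\tseq\n")
        for m in markers:
            fh.write(f"{m.marker_id}\t{m.chromosome}\t{m.cm_position:g}\t{m.seq}\n")


_HIT_COLUMNS = 12


def write_hit_table(rows: Iterable[HitTableRow], path: str | Path) -> None:
    """Write hits in the classic 12-column tab-delimited dialect.

    Column order: query, subject, %identity, alignment length, mismatches,
    gap opens, q.start, q.end, s.start, s.end, frame, score.  Identity is
    fixed to two decimals; coordinates go out 1-based inclusive.
    """
    with open(path, "w") as fh:
        for r in rows:
            q1, q2 = to_disk_coord(r.q_start, r.q_end)
            s1, s2 = to_disk_coord(r.s_start, r.s_end)
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.pct_identity:.2f}\t{r.aln_len_aa}\t"
                f"{r.mismatches}\t{r.gap_opens}\t{q1}\t{q2}\t{s1}\t{s2}\t{r.frame}\t{r.score:g}\n"
            )


def read_hit_table(path: str | Path) -> list[HitTableRow]:
    rows: list[HitTableRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(fields)}"
                )
            q_start, q_end = from_disk_coord(int(fields[6]), int(fields[7]))
            s_start, s_end = from_disk_coord(int(fields[8]), int(fields[9]))
            rows.append(
                HitTableRow(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_len_aa=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    frame=int(fields[10]),
                    score=float(fields[11]),
                )
            )
    return rows
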