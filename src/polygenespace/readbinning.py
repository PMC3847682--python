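"""Repeat pre-filtering of shotgun reads and their allocation to OGRs.

Reads are first screened against a repeat library by exact k-mer masking:
a read survives only if it keeps a repeat-free run of at least 100 bp, and
that longest clean run is what goes into alignment.  Surviving reads are
aligned in all six reading frames against the orthologous group
representative proteins; hits shorter than 30 aligned amino acids or below
the per-reference-species identity threshold are discarded, and each read
is assigned to the OGR of its single best remaining hit (first-best hit,
FBH), so the resulting bins partition the assigned reads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Seq import Seq

from . import _align
from .io_formats import HitTableRow, SequenceRecord

logger = logging.getLogger("polygenespace")


@dataclass
class BinningConfig:
    min_aln_len_aa: int = 30
    identity_threshold: dict[str, float] = field(default_factory=lambda: {"default": 70.0})
    repeat_filter: bool = True

    def __post_init__(self) -> None:
        for sp, t in self.identity_threshold.items():
            if not 0 < t <= 100:
                raise ValueError(f"identity threshold for {sp!r} must be in (0, 100]")


@dataclass
class ReadBin:
    ogr_id: str
    read_ids: set[str] = field(default_factory=set)

    @property
    def total_reads(self) -> int:
        return len(self.read_ids)


def mask_repeats(
    reads: Sequence[SequenceRecord],
    repeat_library: Sequence[SequenceRecord],
    k: int = 20,
    min_free_len: int = 100,
) -> list[SequenceRecord]:
    """Mask repeat-derived read positions and keep reads with a clean run.

    Positions covered by an exact k-mer match to the library (either
    strand) are masked.  A read survives iff its longest unmasked run is
    >= ``min_free_len``; the surviving record carries only that run (the
    part worth aligning), with quals trimmed accordingly.
    """
    if k < 12:
        raise ValueError("k must be >= 12")
    if not repeat_library:
        warnings.warn("empty repeat library: repeat filter is a pass-through")
        return list(reads)
    kmers: set[str] = set()
    for rep in repeat_library:
        for variant in (rep.seq, str(Seq(rep.seq).reverse_complement())):
            for i in range(len(variant) - k + 1):
                kmers.add(variant[i : i + k])
    survivors: list[SequenceRecord] = []
    for read in reads:
        seq = read.seq
        masked = bytearray(len(seq))
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in kmers:
                for j in range(i, i + k):
                    masked[j] = 1
        best_start, best_len = 0, 0
        run_start, run_len = 0, 0
        for i in range(len(seq) + 1):
            if i < len(seq) and not masked[i]:
                if run_len == 0:
                    run_start = i
                run_len += 1
            else:
                if run_len > best_len:
                    best_start, best_len = run_start, run_len
                run_len = 0
        if best_len >= min_free_len:
            qual = read.qual[best_start : best_start + best_len] if read.qual else None
            survivors.append(
                SequenceRecord(read.id, seq[best_start : best_start + best_len], qual)
            )
    return survivors


def translated_align(
    read: SequenceRecord,
    ogr_protein: SequenceRecord,
) -> list[HitTableRow]:
    """Align a nucleotide read against a protein in all six frames.

    Frames are broken at stop codons; each resulting peptide segment is
    locally aligned with BLOSUM62.  Hits carry the frame, percent identity
    over aligned columns, aligned length in amino acids, and coordinates
    on both sequences (query coordinates in nucleotides on the forward
    strand).
    """
    if len(read.seq) < 3:
        raise ValueError("read shorter than one codon")
    return _align_segments(
        read.id, _align.six_frame_segments(read.seq), ogr_protein
    )


def _align_segments(
    read_id: str,
    segments: Sequence[tuple[int, str, int]],
    ogr_protein: SequenceRecord,
) -> list[HitTableRow]:
    hits: list[HitTableRow] = []
    for frame, peptide, nt_start in segments:
        for hit in _align.repeated_local_hits(peptide, ogr_protein.seq):
            if frame > 0:
                q_start = nt_start + 3 * hit.q_start
                q_end = nt_start + 3 * hit.q_end
            else:
                seg_len_nt = 3 * len(peptide)
                q_start = nt_start + seg_len_nt - 3 * hit.q_end
                q_end = nt_start + seg_len_nt - 3 * hit.q_start
            hits.append(
                HitTableRow(
                    query_id=read_id,
                    subject_id=ogr_protein.id,
                    pct_identity=hit.pct_identity,
                    aln_len_aa=hit.aln_columns,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=hit.s_start,
                    s_end=hit.s_end,
                    frame=frame,
                    score=hit.score,
                    mismatches=hit.mismatches,
                    gap_opens=hit.gap_opens,
                )
            )
    hits.sort(key=lambda h: (-h.score, -h.aln_len_aa, h.frame))
    return hits


def translated_align_all(
    reads: Sequence[SequenceRecord],
    ogr_proteins: Sequence[SequenceRecord],
    seed_k: int = 5,
    min_seeds: int = 1,
) -> dict[str, list[HitTableRow]]:
    """Six-frame alignment of many reads against many OGR proteins.

    Uses an exact peptide k-mer index so each frame segment is only
    aligned against proteins it shares seeds with.
    """
    proteins = {p.id: p for p in ogr_proteins}
    index = _align.PeptideIndex({p.id: p.seq for p in ogr_proteins}, k=seed_k)
    per_read: dict[str, list[HitTableRow]] = {}
    for read in reads:
        if len(read.seq) < 3:
            continue
        # only align a frame segment against proteins it shares seeds with
        segs_by_protein: dict[str, list[tuple[int, str, int]]] = {}
        for seg in _align.six_frame_segments(read.seq):
            for pid in index.candidates(seg[1], min_seeds=min_seeds):
                segs_by_protein.setdefault(pid, []).append(seg)
        hits: list[HitTableRow] = []
        for pid in sorted(segs_by_protein):
            hits.extend(_align_segments(read.id, segs_by_protein[pid], proteins[pid]))
        if hits:
            hits.sort(key=lambda h: (-h.score, -h.aln_len_aa, h.subject_id))
            per_read[read.id] = hits
    return per_read


def filter_hits(
    hits: Iterable[HitTableRow],
    cfg: BinningConfig,
    species_of_subject: Optional[Mapping[str, str]] = None,
) -> list[HitTableRow]:
    """Apply the minimum-length (>=30 aa) and per-species identity filters.

    Thresholds are inclusive.  The subject's species is looked up in
    ``species_of_subject`` (falling back to "default"); an unknown species
    key without a default threshold is an error.
    """
    kept = []
    for h in hits:
        species = (species_of_subject or {}).get(h.subject_id, "default")
        if species not in cfg.identity_threshold:
            if "default" in cfg.identity_threshold:
                species = "default"
            else:
                raise KeyError(f"no identity threshold for species {species!r}")
        if h.aln_len_aa >= cfg.min_aln_len_aa and h.pct_identity >= cfg.identity_threshold[species]:
            kept.append(h)
    return kept


def assign_fbh(per_read_hits: Mapping[str, Sequence[HitTableRow]]) -> list[ReadBin]:
    """Assign each read to the OGR of its first-best hit.

    Best = maximum score; ties fall to longer alignment, then to the
    lexicographically smallest OGR id.  Reads without hits stay unbinned.
    """
    bins: dict[str, ReadBin] = {}
    for read_id in sorted(per_read_hits):
        hits = per_read_hits[read_id]
        if not hits:
            continue
        best = max(hits, key=lambda h: (h.score, h.aln_len_aa, _ReverseStr(h.subject_id)))
        bins.setdefault(best.subject_id, ReadBin(best.subject_id)).read_ids.add(read_id)
    return [bins[k] for k in sorted(bins)]


class _ReverseStr(str):
    """String ordered in reverse, so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def bin_reads(
    reads: Sequence[SequenceRecord],
    ogr_proteins: Sequence[SequenceRecord],
    repeat_library: Sequence[SequenceRecord] = (),
    cfg: Optional[BinningConfig] = None,
    species_of_subject: Optional[Mapping[str, str]] = None,
) -> tuple[list[ReadBin], dict[str, SequenceRecord]]:
    """Full binning pipeline: repeat filter, translated alignment, FBH.

    Returns the bins plus the (possibly trimmed) surviving reads by id.
    """
    cfg = cfg or BinningConfig()
    if cfg.repeat_filter and repeat_library:
        surviving = mask_repeats(reads, repeat_library)
    else:
        surviving = list(reads)
    per_read = translated_align_all(surviving, ogr_proteins)
    filtered = {
        rid: kept
        for rid, hits in per_read.items()
        if (kept := filter_hits(hits, cfg, species_of_subject))
    }
    bins = assign_fbh(filtered)
    return bins, {r.id: r for r in surviving}
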