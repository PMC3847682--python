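"""Stringent per-bin overlap assembly controlled by minimum overlap identity.

Each OGR read bin is assembled independently: suffix-prefix (or
containment) overlaps of at least ``min_overlap_bp`` whose alignment
identity reaches the ``mi`` parameter become edges of an overlap graph;
greedy best-overlap-first merging turns the graph into layouts; a
per-column majority vote (quality-weighted when qualities are present)
produces the consensus.  The emitted "sub-assembly" set combines contigs
(>= ``min_contig_bp``) and singleton reads.  ``mi`` is the critical dial:
too low collapses diverged homeologous copies into one contig, too high
splits a single copy on sequencing errors.

Excluded reads fall into three operational categories: ultra-short
(< ``min_read_bp``), over-represented (k-mer spectrum more than 10x the
bin-median depth — repeat-derived), and containment outliers (aligned to
their layout consensus below ``mi`` - 5 identity points).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import _align
from .io_formats import SequenceRecord


@dataclass
class AssemblyConfig:
    mi: float = 99.0
    min_overlap_bp: int = 40
    min_contig_bp: int = 100
    min_read_bp: int = 50
    overlap_k: int = 16
    depth_excess: float = 10.0
    outlier_margin: float = 5.0
    merge_margin: float = 0.0
    consistency_min_len: int = 100
    correct_errors: bool = True
    correction_k: int = 21
    solid_depth: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.mi <= 100:
            raise ValueError("mi must be in (0, 100]")
        if self.min_contig_bp < 1:
            raise ValueError("min_contig_bp must be >= 1")


@dataclass(frozen=True)
class Overlap:
    """b aligned onto a: b (in orientation ``strand``) starts at ``offset``
    in a's coordinates; negative offsets mean b hangs off a's left end."""

    a_id: str
    b_id: str
    strand: int  # +1: b forward, -1: b reverse-complemented
    offset: int
    length: int
    identity: float


@dataclass
class SubAssembly:
    id: str
    seq: str
    kind: str  # "contig" | "singleton"
    member_reads: list[str]
    bin: str = ""

    def __post_init__(self) -> None:
        if self.kind == "contig" and len(self.member_reads) < 2:
            raise ValueError("a contig needs at least two member reads")
        if self.kind == "singleton" and len(self.member_reads) != 1:
            raise ValueError("a singleton has exactly one member read")


@dataclass
class AssemblyStats:
    n_assembled: int = 0
    n_singleton: int = 0
    n_excluded: int = 0

    @property
    def total(self) -> int:
        return self.n_assembled + self.n_singleton + self.n_excluded


def _overlap_identity(a: str, b: str) -> float:
    pct, _ = _align.nt_identity(a, b)
    return pct


def find_overlaps(reads: Sequence[SequenceRecord], cfg: AssemblyConfig) -> list[Overlap]:
    """Detect pairwise overlaps meeting the length and identity thresholds.

    Candidate offsets come from shared exact k-mers (diagonal voting on
    both strands); each candidate is verified with an edit-distance
    alignment of the overlapping substrings, identity measured over the
    alignment including indel columns.
    """
    k = cfg.overlap_k
    order = sorted(range(len(reads)), key=lambda i: reads[i].id)
    seqs = [reads[i].seq for i in order]
    ids = [reads[i].id for i in order]
    buckets: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(seqs):
        for p in range(len(s) - k + 1):
            buckets.setdefault(s[p : p + k], []).append((i, p))
    votes: dict[tuple[int, int, int], Counter] = {}
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        for x in range(len(bucket)):
            i, pi = bucket[x]
            for y in range(x + 1, len(bucket)):
                j, pj = bucket[y]
                if i == j:
                    continue
                a, b = (i, j) if i < j else (j, i)
                pa, pb = (pi, pj) if i < j else (pj, pi)
                votes.setdefault((a, b, 1), Counter())[pa - pb] += 1
    for j, s in enumerate(seqs):
        rc = str(Seq(s).reverse_complement())
        for p in range(len(rc) - k + 1):
            for i, pi in buckets.get(rc[p : p + k], ()):
                if i == j:
                    continue
                if i < j:
                    votes.setdefault((i, j, -1), Counter())[pi - p] += 1
    overlaps: list[Overlap] = []
    for (i, j, strand), counter in votes.items():
        best: Optional[Overlap] = None
        for diag, _n in counter.most_common(3):
            a_seq = seqs[i]
            b_seq = seqs[j] if strand == 1 else str(Seq(seqs[j]).reverse_complement())
            d = diag
            if d >= 0:
                length = min(len(a_seq) - d, len(b_seq))
                sub_a, sub_b = a_seq[d : d + length], b_seq[:length]
            else:
                length = min(len(a_seq), len(b_seq) + d)
                sub_a, sub_b = a_seq[:length], b_seq[-d : -d + length]
            if length < cfg.min_overlap_bp:
                continue
            identity = _overlap_identity(sub_a, sub_b)
            if identity < cfg.mi:
                continue
            cand = Overlap(ids[i], ids[j], strand, d, length, identity)
            # identity first: a diagonal off by one aligns nearly as long
            # but strictly worse, and a wrong offset corrupts the layout
            if best is None or (cand.identity, cand.length) > (best.identity, best.length):
                best = cand
        if best is not None:
            overlaps.append(best)
    overlaps.sort(key=lambda o: (-o.length, -o.identity, o.a_id, o.b_id))
    return overlaps


class _Layout:
    """Reads placed on a shared coordinate axis: id -> (offset, strand)."""

    def __init__(self, read_id: str):
        self.placements: dict[str, tuple[int, int]] = {read_id: (0, 1)}

    def shift(self, delta: int) -> None:
        self.placements = {r: (o + delta, s) for r, (o, s) in self.placements.items()}

    def flip(self, axis_len_lookup) -> None:
        """Reverse-complement the whole layout."""
        new = {}
        for r, (o, s) in self.placements.items():
            length = axis_len_lookup(r)
            new[r] = (-(o + length), -s)
        self.placements = new


def _merge_layouts(
    layouts: dict[str, _Layout],
    overlaps: Sequence[Overlap],
    reads_by_id: dict[str, SequenceRecord],
    cfg: Optional[AssemblyConfig] = None,
) -> list[_Layout]:
    """Greedy best-overlap-first merging; overlap order is the priority.

    When ``cfg`` is given, a merge is committed only if every long implied
    read-vs-read overlap in the merged layout keeps an identity of at
    least ``mi`` - ``merge_margin``: a single short chance overlap between
    two otherwise diverged layouts (e.g. homeologous copies) must not
    bridge them.
    """
    read_len = {r: len(rec.seq) for r, rec in reads_by_id.items()}
    for ov in overlaps:
        la, lb = layouts[ov.a_id], layouts[ov.b_id]
        if la is lb:
            continue
        oa, sa = la.placements[ov.a_id]
        ob, sb = lb.placements[ov.b_id]
        # orient b's layout so that read b has strand sa*ov.strand
        target_strand = sa * ov.strand
        if sb != target_strand:
            lb.flip(lambda r: read_len[r])
            ob, sb = lb.placements[ov.b_id]
        # place read b at offset oa + sa-adjusted ov.offset
        if sa == 1:
            want_ob = oa + ov.offset
        else:
            want_ob = oa + read_len[ov.a_id] - (ov.offset + read_len[ov.b_id])
        delta = want_ob - ob
        if cfg is not None and not _merge_consistent(la, lb, delta, reads_by_id, cfg):
            continue
        lb.shift(delta)
        la.placements.update(lb.placements)
        for r in lb.placements:
            layouts[r] = la
    uniq: list[_Layout] = []
    seen: set[int] = set()
    for lay in layouts.values():
        if id(lay) not in seen:
            seen.add(id(lay))
            uniq.append(lay)
    return uniq


def _oriented(rec: SequenceRecord, strand: int) -> str:
    return rec.seq if strand == 1 else str(Seq(rec.seq).reverse_complement())


def _merge_consistent(
    la: _Layout,
    lb: _Layout,
    delta: int,
    reads_by_id: dict[str, SequenceRecord],
    cfg: AssemblyConfig,
) -> bool:
    """Check all long implied overlaps between two layouts before merging."""
    threshold = cfg.mi - cfg.merge_margin
    for rb, (ob, sb) in lb.placements.items():
        b_start = ob + delta
        b_seq = _oriented(reads_by_id[rb], sb)
        for ra, (oa, sa) in la.placements.items():
            a_seq = _oriented(reads_by_id[ra], sa)
            lo = max(oa, b_start)
            hi = min(oa + len(a_seq), b_start + len(b_seq))
            if hi - lo < cfg.consistency_min_len:
                continue
            sub_a = a_seq[lo - oa : hi - oa]
            sub_b = b_seq[lo - b_start : hi - b_start]
            if _overlap_identity(sub_a, sub_b) < threshold:
                return False
    return True


def _consensus(
    layout: _Layout, reads_by_id: dict[str, SequenceRecord]
) -> tuple[str, int]:
    """Per-column majority-vote consensus (quality-weighted); returns
    (sequence, layout start offset)."""
    lo = min(o for o, _ in layout.placements.values())
    hi = max(o + len(reads_by_id[r].seq) for r, (o, _) in layout.placements.items())
    n = hi - lo
    weights: list[dict[str, float]] = [dict() for _ in range(n)]
    for r, (o, s) in layout.placements.items():
        rec = reads_by_id[r]
        seq = rec.seq if s == 1 else str(Seq(rec.seq).reverse_complement())
        qual = rec.qual if rec.qual is not None else None
        if qual is not None and s == -1:
            qual = qual[::-1]
        for i, base in enumerate(seq):
            col = o - lo + i
            w = float(qual[i]) if qual is not None else 1.0
            weights[col][base] = weights[col].get(base, 0.0) + w
    out = []
    for col in weights:
        if not col:
            out.append("N")
        else:
            out.append(max(sorted(col), key=lambda b: col[b]))
    return "".join(out), lo


def assemble_bin(
    reads: Sequence[SequenceRecord],
    cfg: Optional[AssemblyConfig] = None,
    bin_id: str = "",
) -> tuple[list[SubAssembly], AssemblyStats]:
    """Assemble one read bin into contigs and singletons.

    Deterministic given input read ids (overlaps are processed longest
    first, ties by identity then read-id pair).  Contigs shorter than
    ``min_contig_bp`` are dropped from the output but their reads still
    count as assembled.
    """
    cfg = cfg or AssemblyConfig()
    stats = AssemblyStats()
    usable: list[SequenceRecord] = []
    for r in sorted(reads, key=lambda x: x.id):
        if len(r.seq) < cfg.min_read_bp:
            stats.n_excluded += 1
        else:
            usable.append(r)
    usable = _drop_overrepresented(usable, cfg, stats)
    if not usable:
        return [], stats
    if cfg.correct_errors:
        usable = _error_correct(usable, cfg)
    reads_by_id = {r.id: r for r in usable}
    overlaps = find_overlaps(usable, cfg)
    layouts = {r.id: _Layout(r.id) for r in usable}
    merged = _merge_layouts(layouts, overlaps, reads_by_id, cfg)

    # pass-1 pieces: consensus per layout, with containment-outlier removal
    pieces: list[tuple[str, list[str]]] = []  # (sequence, member read ids)
    for lay in sorted(merged, key=lambda l: min(l.placements)):
        members = sorted(lay.placements)
        if len(members) == 1:
            pieces.append((reads_by_id[members[0]].seq, members))
            continue
        seq, lo = _consensus(lay, reads_by_id)
        keep_members, n_outlier = _split_outliers(lay, seq, lo, reads_by_id, cfg)
        stats.n_excluded += n_outlier
        if len(keep_members) != len(members):
            if not keep_members:
                continue
            sub = _Layout(keep_members[0])
            sub.placements = {r: lay.placements[r] for r in keep_members}
            seq, lo = _consensus(sub, reads_by_id)
        pieces.append((seq, keep_members))

    # pass 2 (iterated): merge pieces at the consensus level — majority
    # vote has averaged away read errors, so borderline same-copy
    # overlaps heal while diverged copies stay apart; repeat until stable
    for _ in range(3):
        piece_recs = [
            SequenceRecord(f"p{i:04d}", seq) for i, (seq, _) in enumerate(pieces)
        ]
        piece_members = {f"p{i:04d}": mem for i, (_, mem) in enumerate(pieces)}
        piece_by_id = {p.id: p for p in piece_recs}
        overlaps2 = find_overlaps(piece_recs, cfg)
        layouts2 = {p.id: _Layout(p.id) for p in piece_recs}
        merged2 = _merge_layouts(layouts2, overlaps2, piece_by_id, cfg)
        if len(merged2) == len(pieces):
            break
        new_pieces: list[tuple[str, list[str]]] = []
        for lay in sorted(merged2, key=lambda l: min(l.placements)):
            piece_ids = sorted(lay.placements)
            members = sorted({r for pid in piece_ids for r in piece_members[pid]})
            if len(piece_ids) == 1:
                seq = piece_by_id[piece_ids[0]].seq
            else:
                seq, _ = _consensus(lay, piece_by_id)
            new_pieces.append((seq, members))
        pieces = new_pieces

    out: list[SubAssembly] = []
    n_contig = 0
    n_singleton = 0
    for lay in sorted(merged2, key=lambda l: min(l.placements)):
        piece_ids = sorted(lay.placements)
        members = sorted({r for pid in piece_ids for r in piece_members[pid]})
        if len(piece_ids) == 1:
            seq = piece_by_id[piece_ids[0]].seq
        else:
            seq, _ = _consensus(lay, piece_by_id)
        if len(members) >= 2:
            stats.n_assembled += len(members)
            if len(seq) >= cfg.min_contig_bp:
                out.append(
                    SubAssembly(
                        id=f"{bin_id}contig{n_contig:04d}",
                        seq=seq,
                        kind="contig",
                        member_reads=members,
                        bin=bin_id,
                    )
                )
                n_contig += 1
        elif len(members) == 1:
            stats.n_singleton += 1
            out.append(
                SubAssembly(
                    id=f"{bin_id}singleton{n_singleton:04d}",
                    seq=reads_by_id[members[0]].seq,
                    kind="singleton",
                    member_reads=members,
                    bin=bin_id,
                )
            )
            n_singleton += 1
    return out, stats


def _error_correct(reads: list[SequenceRecord], cfg: AssemblyConfig) -> list[SequenceRecord]:
    """k-mer spectrum error correction within one bin.

    A k-mer supported by at least ``solid_depth`` occurrences (either
    strand, across the bin) is solid.  An isolated substitution error
    produces a short run of weak k-mers flanked by solid ones; the single
    base substitution that re-solidifies the run is applied.  Diverged
    copy-specific variants are untouched: their k-mers are supported at
    that copy's own depth.  Runs longer than k (divergent or low-coverage
    stretches) are left alone.
    """
    k = cfg.correction_k
    counts: Counter = Counter()
    for r in reads:
        for s in (r.seq, str(Seq(r.seq).reverse_complement())):
            for p in range(len(s) - k + 1):
                counts[s[p : p + k]] += 1

    def solid(km: str) -> bool:
        return counts[km] >= cfg.solid_depth

    out: list[SequenceRecord] = []
    for r in reads:
        n = len(r.seq)
        if n < k + 2:
            out.append(r)
            continue
        seq = list(r.seq)
        weak = [not solid(r.seq[p : p + k]) for p in range(n - k + 1)]
        m = len(weak)
        p = 0
        while p < m:
            if not weak[p]:
                p += 1
                continue
            a = p
            while p < m and weak[p]:
                p += 1
            b = p - 1
            if b - a + 1 > k:
                continue
            run = range(a, b + 1)
            # an error at base i weakens k-mers [i-k+1, i]; candidates
            # are bases covered by every weak k-mer of the run
            candidates = range(b, min(a + k, n))
            best = None
            for i in candidates:
                orig = seq[i]
                for alt in "ACGT":
                    if alt == orig:
                        continue
                    seq[i] = alt
                    gain = sum(1 for q in run if solid("".join(seq[q : q + k])))
                    if gain and (best is None or gain > best[0]):
                        best = (gain, i, alt)
                seq[i] = orig
            if best is not None and best[0] >= max(1, (b - a + 1) // 2):
                seq[best[1]] = best[2]
                for q in run:
                    weak[q] = not solid("".join(seq[q : q + k]))
        out.append(SequenceRecord(r.id, "".join(seq), r.qual))
    return out


def _drop_overrepresented(
    reads: list[SequenceRecord], cfg: AssemblyConfig, stats: AssemblyStats
) -> list[SequenceRecord]:
    """Exclude reads whose k-mer depth within the bin exceeds the bin
    median by ``depth_excess`` (repeat-derived reads)."""
    if len(reads) < 4:
        return reads
    k = cfg.overlap_k
    counts: Counter = Counter()
    for r in reads:
        for p in range(len(r.seq) - k + 1):
            counts[r.seq[p : p + k]] += 1
    mean_depth = []
    for r in reads:
        kmers = [counts[r.seq[p : p + k]] for p in range(len(r.seq) - k + 1)]
        mean_depth.append(float(np.mean(kmers)) if kmers else 0.0)
    median = float(np.median(mean_depth))
    if median <= 0:
        return reads
    keep = []
    for r, d in zip(reads, mean_depth):
        if d > cfg.depth_excess * median:
            stats.n_excluded += 1
        else:
            keep.append(r)
    return keep


def _split_outliers(
    layout: _Layout,
    consensus: str,
    lo: int,
    reads_by_id: dict[str, SequenceRecord],
    cfg: AssemblyConfig,
) -> tuple[list[str], int]:
    """Drop member reads aligning to the consensus below mi - outlier_margin."""
    keep = []
    n_out = 0
    for rid in sorted(layout.placements):
        o, s = layout.placements[rid]
        rec = reads_by_id[rid]
        seq = rec.seq if s == 1 else str(Seq(rec.seq).reverse_complement())
        region = consensus[o - lo : o - lo + len(seq)]
        identity = _overlap_identity(seq, region)
        if identity < cfg.mi - cfg.outlier_margin:
            n_out += 1
        else:
            keep.append(rid)
    return keep, n_out


def assemble_bins(
    bins: dict[str, list[SequenceRecord]],
    cfg: Optional[AssemblyConfig] = None,
) -> tuple[dict[str, list[SubAssembly]], dict[str, AssemblyStats]]:
    """Assemble every bin independently (sorted by bin id for determinism)."""
    out: dict[str, list[SubAssembly]] = {}
    stats: dict[str, AssemblyStats] = {}
    for bid in sorted(bins):
        subs, st = assemble_bin(bins[bid], cfg, bin_id=f"{bid}:")
        out[bid] = subs
        stats[bid] = st
    return out, stats


def assembly_sweep(
    bins: dict[str, list[SequenceRecord]],
    mi_values: Sequence[float] = (97.0, 99.0, 100.0),
    base_cfg: Optional[AssemblyConfig] = None,
) -> pd.DataFrame:
    """Assemble the same bins at several mi values; one stats row per mi.

    On identical input the assembled-read fraction is non-increasing in mi
    and the singleton fraction non-decreasing.
    """
    base_cfg = base_cfg or AssemblyConfig()
    rows = []
    for mi in mi_values:
        cfg = replace(base_cfg, mi=mi)
        _, stats = assemble_bins(bins, cfg)
        agg = AssemblyStats(
            sum(s.n_assembled for s in stats.values()),
            sum(s.n_singleton for s in stats.values()),
            sum(s.n_excluded for s in stats.values()),
        )
        rows.append(
            {
                "mi": mi,
                "n_assembled": agg.n_assembled,
                "n_singleton": agg.n_singleton,
                "n_excluded": agg.n_excluded,
            }
        )
    return pd.DataFrame(rows)
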