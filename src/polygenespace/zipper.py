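"""Virtual gene-order construction along a genetic-marker backbone.

For an unassembled target chromosome, a linear gene order ("zipper") is
inferred by combining (i) a genetic marker map giving the backbone order
in centiMorgan, (ii) one or more sequenced reference genomes whose gene
order is conserved in syntenic blocks, and (iii) repeat-filtered NGS
survey sequences.  Markers are tied to reference genes by bidirectional
best translated hits; the reference genes lying between two consecutive
anchored markers are projected, in reference order, into the interval
(from the highest-ranked reference having both anchors); NGS sequences
attach to the row of their first-best-hit gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from . import _align
from .io_formats import HitTableRow, MarkerRecord, SequenceRecord
from .readbinning import BinningConfig, filter_hits, translated_align_all

logger = logging.getLogger("polygenespace")


@dataclass
class SyntenyBlock:
    reference_id: str
    start_index: int  # gene indices on the reference order, inclusive
    end_index: int
    query_ids: set[str] = field(default_factory=set)
    support: int = 0

    def __contains__(self, gene_index: int) -> bool:
        return self.start_index <= gene_index <= self.end_index


@dataclass
class ZipperRow:
    position_index: int
    marker_id: Optional[str] = None
    cm: Optional[float] = None
    ref_gene_ids: dict[str, str] = field(default_factory=dict)
    anchored_ngs_ids: list[str] = field(default_factory=list)
    inverted: bool = False


@dataclass
class ZipperResult:
    rows: list[ZipperRow]
    unplaced_genes: dict[str, list[str]]
    unplaced_ngs: list[str]


def _fbh_to_genes(
    query_seqs: Sequence[SequenceRecord],
    reference_genes: Sequence[SequenceRecord],
    identity_min: float,
    min_len_aa: int,
) -> dict[str, HitTableRow]:
    """First-best translated hit per query against the reference proteins."""
    cfg = BinningConfig(
        min_aln_len_aa=min_len_aa, identity_threshold={"default": identity_min}
    )
    per_query = translated_align_all(query_seqs, reference_genes)
    best: dict[str, HitTableRow] = {}
    for qid, hits in per_query.items():
        kept = filter_hits(hits, cfg)
        if kept:
            best[qid] = max(
                kept, key=lambda h: (h.score, h.aln_len_aa, _Rev(h.subject_id))
            )
    return best


class _Rev(str):
    """String ordered in reverse, so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def detect_synteny(
    query_seqs: Sequence[SequenceRecord],
    reference_genes: Sequence[SequenceRecord],
    reference_id: str = "ref",
    identity_min: float = 70.0,
    min_len_aa: int = 30,
    window: int = 5,
    min_density: int = 3,
) -> list[SyntenyBlock]:
    """Sliding-window detection of syntenic blocks on the reference gene order.

    ``reference_genes`` must be given in their genomic order (unique ids).
    A window of ``window`` consecutive reference genes qualifies when at
    least ``min_density`` of them receive a first-best query hit;
    overlapping qualifying windows merge into maximal blocks.
    """
    ids = [g.id for g in reference_genes]
    if len(set(ids)) != len(ids):
        raise ValueError("reference gene order contains duplicate ids")
    index_of = {g.id: i for i, g in enumerate(reference_genes)}
    best = _fbh_to_genes(query_seqs, reference_genes, identity_min, min_len_aa)
    hit_queries: dict[int, set[str]] = {}
    for qid, hit in best.items():
        hit_queries.setdefault(index_of[hit.subject_id], set()).add(qid)
    n = len(reference_genes)
    qualifying = []
    for w in range(max(n - window + 1, 1)):
        span = range(w, min(w + window, n))
        if sum(1 for i in span if i in hit_queries) >= min_density:
            qualifying.append((w, min(w + window, n) - 1))
    blocks: list[SyntenyBlock] = []
    for start, end in qualifying:
        if blocks and start <= blocks[-1].end_index + 1:
            blocks[-1].end_index = max(blocks[-1].end_index, end)
        else:
            blocks.append(SyntenyBlock(reference_id, start, end))
    # trim each block to its outermost hit genes and collect support
    out = []
    for b in blocks:
        hit_idx = [i for i in range(b.start_index, b.end_index + 1) if i in hit_queries]
        if not hit_idx:
            continue
        queries: set[str] = set()
        for i in hit_idx:
            queries |= hit_queries[i]
        out.append(
            SyntenyBlock(
                reference_id,
                min(hit_idx),
                max(hit_idx),
                query_ids=queries,
                support=len(hit_idx),
            )
        )
    return out


def anchor_markers(
    markers: Sequence[MarkerRecord],
    reference_genes: Sequence[SequenceRecord],
    identity_min: float = 70.0,
    min_len_aa: int = 30,
) -> dict[str, int]:
    """Bidirectional-best-hit anchoring of markers to reference gene indices.

    Marker m anchors gene g iff g is m's best hit and m is g's best
    marker; non-reciprocal pairs stay unanchored.
    """
    index_of = {g.id: i for i, g in enumerate(reference_genes)}
    marker_seqs = [SequenceRecord(m.marker_id, m.seq) for m in markers]
    best_gene = _fbh_to_genes(marker_seqs, reference_genes, identity_min, min_len_aa)
    # best marker per gene, from the same hit set
    cfg = BinningConfig(min_aln_len_aa=min_len_aa, identity_threshold={"default": identity_min})
    per_query = translated_align_all(marker_seqs, reference_genes)
    best_marker: dict[str, tuple[float, int, str]] = {}
    for mid, hits in per_query.items():
        for h in filter_hits(hits, cfg):
            key = (h.score, h.aln_len_aa, _Rev(mid))
            if h.subject_id not in best_marker or key > best_marker[h.subject_id]:
                best_marker[h.subject_id] = key
    anchors: dict[str, int] = {}
    for mid, hit in best_gene.items():
        bm = best_marker.get(hit.subject_id)
        if bm is not None and str(bm[2]) == mid:
            anchors[mid] = index_of[hit.subject_id]
    return anchors


def anchor_ngs(
    ngs_seqs: Sequence[SequenceRecord],
    reference_genes: Sequence[SequenceRecord],
    identity_min: float = 70.0,
    min_len_aa: int = 30,
) -> dict[str, str]:
    """First-best-hit gene id per NGS sequence."""
    best = _fbh_to_genes(ngs_seqs, reference_genes, identity_min, min_len_aa)
    return {qid: hit.subject_id for qid, hit in best.items()}


def build_zipper(
    marker_map: Sequence[MarkerRecord],
    anchors: Mapping[str, Mapping[str, int]],
    blocks: Mapping[str, Sequence[SyntenyBlock]],
    reference_orders: Mapping[str, Sequence[SequenceRecord]],
    ranking: Sequence[str],
    ngs_anchors: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> ZipperResult:
    """Assemble the virtual gene-order map.

    ``anchors``, ``blocks``, ``reference_orders`` and ``ngs_anchors`` are
    keyed by reference name; ``ranking`` lists references from
    evolutionarily closest to most distant.  Marker order (by cM) is
    preserved exactly; between two consecutive markers the genes of the
    highest-ranked reference anchored at both ends are inserted in
    reference order (reversed, with an inversion flag, when the anchor
    indices contradict the marker order).  Genes are only inserted when
    they lie in a syntenic block, and each gene appears at most once per
    reference column.
    """
    markers = sorted(marker_map, key=lambda m: (m.chromosome, m.cm_position))
    block_genes: dict[str, set[int]] = {
        ref: {i for b in blocks.get(ref, []) for i in range(b.start_index, b.end_index + 1)}
        for ref in ranking
    }
    used_genes: dict[str, set[int]] = {ref: set() for ref in ranking}
    rows: list[ZipperRow] = []
    pos = 0

    def marker_row(m: MarkerRecord) -> ZipperRow:
        nonlocal pos
        genes = {}
        for ref in ranking:
            gi = anchors.get(ref, {}).get(m.marker_id)
            if gi is not None and gi not in used_genes[ref]:
                genes[ref] = reference_orders[ref][gi].id
                used_genes[ref].add(gi)
        row = ZipperRow(pos, m.marker_id, m.cm_position, genes)
        pos += 1
        return row

    for i, m in enumerate(markers):
        rows.append(marker_row(m))
        if i + 1 >= len(markers):
            break
        nxt = markers[i + 1]
        chosen = None
        for ref in ranking:
            a = anchors.get(ref, {}).get(m.marker_id)
            b = anchors.get(ref, {}).get(nxt.marker_id)
            if a is not None and b is not None:
                chosen = (ref, a, b)
                break
        if chosen is None:
            continue
        ref, a, b = chosen
        inverted = a > b
        lo, hi = (b, a) if inverted else (a, b)
        between = [
            gi
            for gi in range(lo + 1, hi)
            if gi in block_genes[ref] and gi not in used_genes[ref]
        ]
        if inverted:
            between.reverse()
        for gi in between:
            rows.append(
                ZipperRow(
                    pos,
                    ref_gene_ids={ref: reference_orders[ref][gi].id},
                    inverted=inverted,
                )
            )
            used_genes[ref].add(gi)
            pos += 1

    unplaced_genes = {
        ref: [
            reference_orders[ref][gi].id
            for gi in sorted(block_genes[ref] - used_genes[ref])
        ]
        for ref in ranking
    }
    unplaced_ngs: list[str] = []
    if ngs_anchors:
        gene_row: dict[tuple[str, str], ZipperRow] = {}
        for row in rows:
            for ref, gid in row.ref_gene_ids.items():
                gene_row[(ref, gid)] = row
        seen: set[str] = set()
        for ref in ranking:
            for nid, gid in sorted(ngs_anchors.get(ref, {}).items()):
                if nid in seen:
                    continue
                row = gene_row.get((ref, gid))
                if row is not None:
                    row.anchored_ngs_ids.append(nid)
                    seen.add(nid)
        all_ngs = {nid for ref in ngs_anchors for nid in ngs_anchors[ref]}
        unplaced_ngs = sorted(all_ngs - seen)
    return ZipperResult(rows, unplaced_genes, unplaced_ngs)


def zipper_table(result: ZipperResult, ranking: Sequence[str]):
    """Flatten a ZipperResult to a pandas DataFrame (one gene column per
    reference, the shape of published virtual gene-order tables)."""
    import pandas as pd

    rows = []
    for r in result.rows:
        row = {
            "position": r.position_index,
            "marker": r.marker_id or "",
            "cM": r.cm if r.cm is not None else "",
            "inverted": r.inverted,
            "anchored_ngs": ",".join(r.anchored_ngs_ids),
        }
        for ref in ranking:
            row[f"gene_{ref}"] = r.ref_gene_ids.get(ref, "")
        rows.append(row)
    return pd.DataFrame(rows)
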