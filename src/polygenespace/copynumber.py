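"""Gene copy-number estimation from position-specific hit-count profiles.

Sub-assemblies are re-aligned to their OGR template protein with the same
filters used for read binning.  Because sub-assemblies may run through
introns or UTRs, co-linear high-scoring segment pairs (HSPs) are chained
into a spliced alignment.  Each template amino-acid position then counts
the number of *distinct* sub-assemblies whose chain covers it (the
hit-count profile); the profile's cumulative coverage distribution over
covered positions yields the copy number: the largest hit count h reached
by at least a fraction C of the covered template.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import HitTableRow, SequenceRecord
from .readbinning import BinningConfig, filter_hits, translated_align
from .subassembly import SubAssembly


@dataclass
class HitCountProfile:
    ogr_id: str
    counts: np.ndarray  # length = template protein length (aa)
    contributing: set[str] = field(default_factory=set)


@dataclass
class CopyNumberCall:
    ogr_id: str
    copy_number: int
    C: float
    covered_positions: int


def spliced_realign(
    sub_assembly: SequenceRecord | SubAssembly,
    ogr_protein: SequenceRecord,
    cfg: Optional[BinningConfig] = None,
    max_overlap_aa: int = 10,
) -> list[HitTableRow]:
    """Align a sub-assembly to the template and chain co-linear HSPs.

    Each HSP must individually pass the binning filters (>= 30 aa,
    identity threshold).  The returned chain is the maximal-score subset
    of HSPs that is strictly increasing on both the template and the
    sub-assembly (same strand), tolerating up to ``max_overlap_aa`` of
    template overlap between consecutive HSPs; unaligned gaps of any
    length (introns, UTRs) are allowed between them.
    """
    cfg = cfg or BinningConfig()
    if isinstance(sub_assembly, SubAssembly):
        rec = SequenceRecord(sub_assembly.id, sub_assembly.seq)
    else:
        rec = sub_assembly
    if len(rec.seq) < 3:
        return []
    hsps = filter_hits(translated_align(rec, ogr_protein), cfg)
    if not hsps:
        return []
    best_chain: list[HitTableRow] = []
    best_score = -1.0
    for strand in (1, -1):
        strand_hsps = [h for h in hsps if (h.frame > 0) == (strand > 0)]
        chain = _max_score_chain(strand_hsps, max_overlap_aa, strand)
        score = sum(h.score for h in chain)
        if score > best_score:
            best_chain, best_score = chain, score
    return best_chain


def _max_score_chain(
    hsps: list[HitTableRow], max_overlap_aa: int, strand: int
) -> list[HitTableRow]:
    """Dynamic program for the maximum-score co-linear HSP chain."""
    if not hsps:
        return []
    hsps = sorted(hsps, key=lambda h: (h.s_start, h.s_end))
    n = len(hsps)
    best = [h.score for h in hsps]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            a, b = hsps[j], hsps[i]
            if b.s_start < a.s_end - max_overlap_aa:
                continue
            # query co-linearity in read orientation
            if strand > 0:
                ok = b.q_start >= a.q_end - 3 * max_overlap_aa
            else:
                ok = b.q_end <= a.q_start + 3 * max_overlap_aa
            if not ok:
                continue
            if best[j] + b.score > best[i]:
                best[i] = best[j] + b.score
                prev[i] = j
    i_best = int(np.argmax(best))
    chain = []
    i = i_best
    while i != -1:
        chain.append(hsps[i])
        i = prev[i]
    chain.reverse()
    return chain


def build_profile(
    chains_by_subassembly: Mapping[str, Sequence[HitTableRow]],
    template_len: int,
    ogr_id: str = "",
) -> HitCountProfile:
    """Count distinct sub-assemblies covering each template position.

    A sub-assembly contributes at most 1 to each position regardless of
    how many HSPs of its chain touch it.
    """
    counts = np.zeros(template_len, dtype=int)
    contributing: set[str] = set()
    for sid in sorted(chains_by_subassembly):
        chain = chains_by_subassembly[sid]
        if not chain:
            continue
        covered = np.zeros(template_len, dtype=bool)
        for h in chain:
            if h.s_end > template_len or h.s_start < 0:
                raise ValueError(
                    f"chain coordinate [{h.s_start},{h.s_end}) beyond template length {template_len}"
                )
            covered[h.s_start : h.s_end] = True
        if covered.any():
            counts += covered
            contributing.add(sid)
    return HitCountProfile(ogr_id=ogr_id, counts=counts, contributing=contributing)


def cumulative_distribution(profile: HitCountProfile) -> dict[int, float]:
    """Fraction of *covered* template positions with hit count >= h.

    Domain is 1..max(counts); an uncovered profile yields an empty map.
    """
    covered = profile.counts[profile.counts >= 1]
    if covered.size == 0:
        return {}
    out = {}
    for h in range(1, int(covered.max()) + 1):
        out[h] = float((covered >= h).sum()) / covered.size
    return out


def estimate_copy_number(profile: HitCountProfile, C: float = 0.9) -> CopyNumberCall:
    """Copy number = max hit count h whose coverage fraction is >= C.

    C is the minimum fraction of the covered template that must reach the
    hit count.  Since fraction(1) is 1.0 by construction, any covered
    template reports at least copy number 1; an uncovered profile reports 0.
    """
    if not 0 < C <= 1:
        raise ValueError("C must be in (0, 1]")
    dist = cumulative_distribution(profile)
    if not dist:
        return CopyNumberCall(profile.ogr_id, 0, C, 0)
    copy_number = max(h for h, frac in dist.items() if frac >= C)
    return CopyNumberCall(
        profile.ogr_id,
        copy_number,
        C,
        covered_positions=int((profile.counts >= 1).sum()),
    )


def copy_number_for_bin(
    sub_assemblies: Sequence[SubAssembly],
    ogr_protein: SequenceRecord,
    cfg: Optional[BinningConfig] = None,
    C: float = 0.9,
) -> tuple[CopyNumberCall, HitCountProfile]:
    """Convenience pipeline: spliced re-alignment, profile, copy number."""
    chains = {
        s.id: spliced_realign(s, ogr_protein, cfg)
        for s in sub_assemblies
    }
    profile = build_profile(chains, len(ogr_protein.seq), ogr_id=ogr_protein.id)
    return estimate_copy_number(profile, C=C), profile
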