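"""Seeded local-alignment primitives shared by binning, clustering and synteny.

Protein alignments use an affine-gap Smith-Waterman (BLOSUM62) behind a
k-mer seed prefilter so that a query is only aligned against subjects it
plausibly matches.  Nucleotide identity is computed from edit-distance
alignments (edlib).  Percent identity is always matches / aligned columns,
with gap columns counted as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# translate() may emit letters outside the BLOSUM alphabet for ambiguous codons
_AA_OK = set("ARNDCQEGHILKMFPSTWYVBZX")


def make_protein_aligner() -> PairwiseAligner:
    # gap extension is deliberately expensive: a local hit must not bridge
    # long unalignable stretches (translated introns/UTRs) with one cheap
    # affine gap — spliced coverage is the chainer's job, not the aligner's
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -6.0
    return aligner


_PROT_ALIGNER = make_protein_aligner()


@dataclass
class LocalHit:
    """Result of one local alignment: coordinates 0-based half-open."""

    score: float
    pct_identity: float
    aln_columns: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


def align_protein_local(query: str, subject: str) -> Optional[LocalHit]:
    """Best local alignment of two amino-acid strings, or None if score <= 0."""
    query = _sanitize_aa(query)
    subject = _sanitize_aa(subject)
    if not query or not subject:
        return None
    alignments = _PROT_ALIGNER.align(query, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    if aln.score <= 0:
        return None
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gaps = counts.gaps
    columns = identities + mismatches + gaps
    if columns == 0:
        return None
    blocks_q, blocks_s = aln.aligned
    gap_opens = max(len(blocks_q) - 1, 0)
    return LocalHit(
        score=float(aln.score),
        pct_identity=100.0 * identities / columns,
        aln_columns=columns,
        mismatches=mismatches + gaps,
        gap_opens=gap_opens,
        q_start=int(blocks_q[0][0]),
        q_end=int(blocks_q[-1][1]),
        s_start=int(blocks_s[0][0]),
        s_end=int(blocks_s[-1][1]),
    )


def repeated_local_hits(
    query: str, subject: str, min_len: int = 15
) -> list[LocalHit]:
    """All non-overlapping (on the query) local hits of query vs subject.

    Repeated Smith-Waterman: take the best local hit, then recurse into
    the unaligned query flanks, keeping hits of at least ``min_len``
    aligned columns.  Needed when one reading-frame segment spans several
    exons separated by an unalignable (intronic) stretch.
    """
    out: list[LocalHit] = []

    def recurse(q: str, q_off: int) -> None:
        if len(q) < min_len:
            return
        hit = align_protein_local(q, subject)
        if hit is None or hit.aln_columns < min_len:
            return
        left = q[: hit.q_start]
        right = q[hit.q_end :]
        right_off = q_off + hit.q_end
        hit.q_start += q_off
        hit.q_end += q_off
        out.append(hit)
        recurse(left, q_off)
        recurse(right, right_off)

    recurse(query, 0)
    out.sort(key=lambda h: h.q_start)
    return out


_SANITIZE_TABLE = str.maketrans(
    {chr(i): ("X" if chr(i).upper() not in _AA_OK else chr(i).upper()) for i in range(128)}
)


def _sanitize_aa(seq: str) -> str:
    return seq.translate(_SANITIZE_TABLE)


def self_score(seq: str) -> float:
    """Score of a sequence aligned to itself (used for score normalization)."""
    seq = _sanitize_aa(seq)
    return float(sum(_BLOSUM62[c, c] for c in seq))


def six_frame_segments(nt: str) -> list[tuple[int, str, int]]:
    """Translate all six frames, splitting at stop codons.

    Returns (frame, peptide, nt_start) triples where ``frame`` is in
    {1,2,3,-1,-2,-3} and ``nt_start`` is the 0-based position on the
    *forward* strand of the first base of the segment's first codon.
    Segments shorter than 10 aa are dropped.
    """
    out: list[tuple[int, str, int]] = []
    n = len(nt)
    rc = str(Seq(nt).reverse_complement())
    for strand, template in ((1, nt), (-1, rc)):
        for off in range(3):
            usable = (len(template) - off) // 3 * 3
            if usable < 3:
                continue
            peptide = str(Seq(template[off : off + usable]).translate())
            frame = (off + 1) * strand
            start = 0
            for part in peptide.split("*"):
                if len(part) >= 10:
                    aa_pos = start  # aa offset within the frame translation
                    nt_pos_in_template = off + 3 * aa_pos
                    if strand == 1:
                        nt_start = nt_pos_in_template
                    else:
                        # last base of the segment on the rc template, mapped back
                        nt_start = n - (nt_pos_in_template + 3 * len(part))
                    out.append((frame, part, nt_start))
                start += len(part) + 1
    return out


def nt_identity(a: str, b: str, mode: str = "NW") -> tuple[float, int]:
    """Percent identity and alignment length of two nucleotide strings.

    ``mode`` follows edlib: "NW" global, "HW" infix (b as reference).
    Identity counts indel columns as mismatches.
    """
    if not a or not b:
        return 0.0, 0
    res = edlib.align(a, b, task="path", mode=mode)
    cigar = res["cigar"]
    matches = 0
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, columns


def best_local_nt_hit(query: str, subject: str) -> Optional[LocalHit]:
    """Best infix alignment of query (or its reverse complement) in subject."""
    best: Optional[LocalHit] = None
    rc = str(Seq(query).reverse_complement())
    for q in (query, rc):
        res = edlib.align(q, subject, task="path", mode="HW")
        if res["editDistance"] < 0:
            continue
        pct, columns = _cigar_identity(res["cigar"])
        if columns == 0:
            continue
        loc = res["locations"][0]
        matches = round(pct / 100.0 * columns)
        hit = LocalHit(
            score=float(matches),
            pct_identity=pct,
            aln_columns=columns,
            mismatches=columns - matches,
            gap_opens=0,
            q_start=0,
            q_end=len(q),
            s_start=int(loc[0]),
            s_end=int(loc[1]) + 1,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def _cigar_identity(cigar: str) -> tuple[float, int]:
    matches = 0
    columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, columns


class PeptideIndex:
    """Exact k-mer index over a set of proteins for seed prefiltering."""

    def __init__(self, proteins: dict[str, str], k: int = 5):
        self.k = k
        self.proteins = proteins
        self._index: dict[str, set[str]] = {}
        for pid, seq in proteins.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], set()).add(pid)

    def candidates(self, peptide: str, min_seeds: int = 1) -> list[str]:
        """Subject ids sharing >= min_seeds exact k-mers with the peptide."""
        hits: dict[str, int] = {}
        k = self.k
        for i in range(len(peptide) - k + 1):
            for pid in self._index.get(peptide[i : i + k], ()):
                hits[pid] = hits.get(pid, 0) + 1
        return sorted(pid for pid, n in hits.items() if n >= min_seeds)
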