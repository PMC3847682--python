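"""Seeded generators for calibration experiments and test fixtures.

Two study designs are reproduced: (i) a whole-genome shotgun experiment on
a diploid gene space (genes with introns/UTRs embedded in repeat-laden
intergenic sequence, 5x 454-like reads with a uniform 0.5% substitution
error), and (ii) a polyploid gene catalogue in which each transcript is
replicated ``ploidy_factor`` times and single-nucleotide variants are
injected at per-base rates of 0.01 in coding and 0.04 in non-coding
sequence, emulating homeolog divergence in an allo-hexaploid.

All generators are byte-deterministic for a fixed seed.  Read ids carry
their provenance (template, start, strand) for truth tracking; downstream
modules must never parse it outside of tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from . import _align
from .io_formats import SequenceRecord

_NT = np.array(list("ACGT"))
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if Seq(a + b + c).translate() != "*"
]
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Parameters of the simulated sequencing experiment.

    Defaults mirror the calibration design: 5x genome coverage, uniform
    0.5% per-base substitution error, triplication of the gene catalogue
    with SNV rates of 1/100 bp (coding) and 4/100 bp (non-coding).
    """

    coverage: float = 5.0
    error_rate: float = 0.005
    read_len_mean: float = 400.0
    read_len_sd: float = 100.0
    ploidy_factor: int = 3
    snv_coding: float = 0.01
    snv_noncoding: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if self.ploidy_factor < 1:
            raise ValueError("ploidy_factor must be a positive integer")


@dataclass
class GeneModel:
    """A protein-coding gene placed on a simulated chromosome."""

    gene_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, on the chromosome
    utr5: int
    utr3: int
    protein: str
    family_id: str = ""

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        if any(e <= s for s, e in self.exons):
            raise ValueError("exon end must exceed start")
        if starts != sorted(starts) or any(
            self.exons[i][1] > self.exons[i + 1][0] for i in range(len(self.exons) - 1)
        ):
            raise ValueError("exons must be non-overlapping and ascending")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0] - self.utr5, self.exons[-1][1] + self.utr3


@dataclass
class Transcript:
    """An unspliced gene sequence (UTRs + exons + introns) with coding intervals."""

    id: str
    seq: str
    coding: list[tuple[int, int]]  # 0-based half-open, on self.seq
    family_id: str = ""

    def __post_init__(self) -> None:
        if not self.coding:
            raise ValueError(f"transcript {self.id!r} has no coding annotation")


@dataclass
class TruthTable:
    """True copy counts per gene family after redundancy collapsing."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("truth counts must be >= 1")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG + random non-stop codons + stop."""
    body = "".join(_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons - 2))
    return "ATG" + body + _STOPS[int(rng.integers(0, 3))]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=n)])


def mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability p (uniform over
    the three alternatives)."""
    if p <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in hit:
        base = arr[i].decode()
        alts = [b for b in "ACGT" if b != base]
        arr[i] = alts[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def generate_gene_space(
    n_genes: int,
    *,
    exon_codons: tuple[int, int] = (40, 120),
    n_exons_range: tuple[int, int] = (1, 4),
    intron_len_range: tuple[int, int] = (80, 400),
    utr_len_range: tuple[int, int] = (80, 300),
    spacer_len_range: tuple[int, int] = (300, 800),
    repeat_fraction: float = 0.3,
    multicopy_fraction: float = 0.0,
    max_copies: int = 3,
    copy_divergence: float = 0.03,
    seed: int = 0,
) -> tuple[SequenceRecord, list[GeneModel], list[SequenceRecord]]:
    """Simulate a gene space: one chromosome, gene models and a repeat library.

    Genes are separated by intergenic spacers; ``repeat_fraction`` of each
    spacer is filled with copies drawn from the emitted repeat library
    (exact copies, so k-mer masking can find them).  When
    ``multicopy_fraction`` > 0, that fraction of gene families receives
    2..max_copies members diverged by ``copy_divergence`` substitutions
    per coding base (non-coding parts diverge at twice that rate).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= repeat_fraction < 1:
        raise ValueError("repeat_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    repeat_library: list[SequenceRecord] = []
    if repeat_fraction > 0:
        for i in range(3):
            repeat_library.append(
                SequenceRecord(f"repeat{i}", _random_nt(rng, int(rng.integers(200, 500))))
            )

    # draw family structures
    families: list[list[str]] = []
    gene_counter = 0
    fam_counter = 0
    while gene_counter < n_genes:
        fam_id = f"fam{fam_counter:04d}"
        if rng.random() < multicopy_fraction:
            k = int(rng.integers(2, max_copies + 1))
        else:
            k = 1
        k = min(k, n_genes - gene_counter)
        families.append([fam_id] * k)
        gene_counter += k
        fam_counter += 1

    chrom_parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    gene_idx = 0

    def spacer() -> str:
        n = int(rng.integers(*spacer_len_range))
        if not repeat_library or repeat_fraction == 0:
            return _random_nt(rng, n)
        n_rep = int(n * repeat_fraction)
        parts = []
        filled = 0
        while filled < n_rep:
            rep = repeat_library[int(rng.integers(0, len(repeat_library)))]
            take = min(len(rep.seq), n_rep - filled)
            parts.append(rep.seq[:take])
            filled += take
        parts.append(_random_nt(rng, n - n_rep))
        return "".join(parts)

    for fam_members in families:
        fam_id = fam_members[0]
        n_copies = len(fam_members)
        # base gene structure shared by the family
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        codons = [int(rng.integers(*exon_codons)) for _ in range(n_ex)]
        total_codons = sum(codons)
        cds = _random_cds(rng, total_codons)
        introns = [_random_nt(rng, int(rng.integers(*intron_len_range))) for _ in range(n_ex - 1)]
        utr5 = _random_nt(rng, int(rng.integers(*utr_len_range)))
        utr3 = _random_nt(rng, int(rng.integers(*utr_len_range)))

        for copy_i in range(n_copies):
            if copy_i == 0:
                c_cds, c_introns, c_u5, c_u3 = cds, introns, utr5, utr3
            else:
                c_cds = _mutate_cds_no_stop(cds, copy_divergence, rng)
                c_introns = [mutate(s, 2 * copy_divergence, rng) for s in introns]
                c_u5 = mutate(utr5, 2 * copy_divergence, rng)
                c_u3 = mutate(utr3, 2 * copy_divergence, rng)
            chrom_parts.append(spacer())
            pos = sum(len(p) for p in chrom_parts)
            pos += len(c_u5)
            chrom_parts.append(c_u5)
            exon_coords: list[tuple[int, int]] = []
            cds_off = 0
            for j, n_codon in enumerate(codons):
                exon_nt = c_cds[cds_off : cds_off + 3 * n_codon]
                cds_off += 3 * n_codon
                exon_coords.append((pos, pos + len(exon_nt)))
                chrom_parts.append(exon_nt)
                pos += len(exon_nt)
                if j < n_ex - 1:
                    chrom_parts.append(c_introns[j])
                    pos += len(c_introns[j])
            chrom_parts.append(c_u3)
            protein = str(Seq(c_cds).translate()).rstrip("*")
            genes.append(
                GeneModel(
                    gene_id=f"gene{gene_idx:04d}",
                    exons=exon_coords,
                    utr5=len(c_u5),
                    utr3=len(c_u3),
                    protein=protein,
                    family_id=fam_id,
                )
            )
            gene_idx += 1
    chrom_parts.append(spacer())
    chromosome = SequenceRecord("chr1", "".join(chrom_parts))
    return chromosome, genes, repeat_library


def _mutate_cds_no_stop(cds: str, p: float, rng: np.random.Generator) -> str:
    """Mutate a CDS, resampling any codon that would become a stop."""
    out = []
    for i in range(0, len(cds) - 3, 3):
        codon = mutate(cds[i : i + 3], p, rng)
        while codon in _STOPS:
            codon = mutate(cds[i : i + 3], p, rng)
        out.append(codon)
    out.append(cds[-3:])  # keep the terminal stop
    return "".join(out)


def transcripts_from_gene_space(
    chromosome: SequenceRecord, genes: Sequence[GeneModel]
) -> list[Transcript]:
    """Extract each gene's unspliced transcript (UTR5..UTR3) with coding intervals."""
    out = []
    for g in genes:
        start, end = g.span
        seq = chromosome.seq[start:end]
        coding = [(s - start, e - start) for s, e in g.exons]
        out.append(Transcript(g.gene_id, seq, coding, family_id=g.family_id))
    return out


def simulate_reads(
    templates: Sequence[SequenceRecord], cfg: SimConfig
) -> list[SequenceRecord]:
    """Simulate 454-like shotgun reads from the templates.

    Read count is chosen so total read bases hit ``cfg.coverage`` times the
    total template length (within 2%); lengths are Normal(mean, sd)
    truncated to [50, template length]; both strands are sampled uniformly;
    each base is substituted independently with ``cfg.error_rate``.  Read
    ids encode (template, start, strand) for truth tracking.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    total = sum(len(t) for t in templates)
    target_bases = cfg.coverage * total
    weights = np.array([len(t) for t in templates], dtype=float)
    weights /= weights.sum()
    qual_val = (
        min(int(round(-10 * math.log10(cfg.error_rate))), 40) if cfg.error_rate > 0 else 40
    )
    reads: list[SequenceRecord] = []
    emitted = 0.0
    i = 0
    while emitted < target_bases:
        t = templates[int(rng.choice(len(templates), p=weights))]
        length = int(round(rng.normal(cfg.read_len_mean, cfg.read_len_sd)))
        length = max(50, min(length, len(t)))
        start = int(rng.integers(0, len(t) - length + 1))
        frag = t.seq[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = str(Seq(frag).reverse_complement())
        frag = mutate(frag, cfg.error_rate, rng)
        reads.append(
            SequenceRecord(
                f"read{i:06d}|{t.id}|{start}|{strand}", frag, [qual_val] * len(frag)
            )
        )
        emitted += length
        i += 1
    return reads


def make_polyploid_catalogue(
    transcripts: Sequence[Transcript], cfg: SimConfig
) -> tuple[list[SequenceRecord], TruthTable]:
    """Replicate each transcript ``ploidy_factor`` times with SNVs.

    Coding bases are substituted with probability ``cfg.snv_coding`` and
    non-coding bases with ``cfg.snv_noncoding``; substitutions are uniform
    over the three alternative nucleotides.  The truth table records
    ploidy_factor x (pre-replication copy count per family).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[SequenceRecord] = []
    fam_counts: dict[str, int] = {}
    for t in transcripts:
        fam = t.family_id or t.id
        fam_counts[fam] = fam_counts.get(fam, 0) + 1
        coding_mask = np.zeros(len(t.seq), dtype=bool)
        for s, e in t.coding:
            if e > len(t.seq):
                raise ValueError(f"coding interval {s, e} beyond transcript {t.id!r}")
            coding_mask[s:e] = True
        for h in range(cfg.ploidy_factor):
            arr = np.frombuffer(t.seq.encode(), dtype="S1").copy()
            p = np.where(coding_mask, cfg.snv_coding, cfg.snv_noncoding)
            hit = np.nonzero(rng.random(len(arr)) < p)[0]
            for idx in hit:
                base = arr[idx].decode()
                alts = [b for b in "ACGT" if b != base]
                arr[idx] = alts[int(rng.integers(0, 3))].encode()
            out.append(SequenceRecord(f"{t.id}_h{h}", arr.tobytes().decode()))
    truth = TruthTable({fam: cfg.ploidy_factor * n for fam, n in fam_counts.items()})
    return out, truth


def collapse_redundancy(
    sequences: Sequence[SequenceRecord], identity_level: float
) -> list[SequenceRecord]:
    """Greedy longest-first redundancy clustering; returns representatives.

    A sequence joins an existing representative when their global
    nucleotide identity is >= ``identity_level`` (a fraction, e.g. 0.97).
    """
    if not 0 < identity_level <= 1:
        raise ValueError("identity_level must be in (0, 1]")
    ordered = sorted(sequences, key=lambda r: (-len(r.seq), r.id))
    reps: list[SequenceRecord] = []
    for rec in ordered:
        merged = False
        for rep in reps:
            pct, _ = _align.nt_identity(rec.seq, rep.seq)
            if pct >= 100.0 * identity_level:
                merged = True
                break
        if not merged:
            reps.append(rec)
    return reps
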