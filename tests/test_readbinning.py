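import numpy as np
import pytest
from Bio.Seq import Seq

from polygenespace.io_formats import HitTableRow, SequenceRecord
from polygenespace.readbinning import (
    BinningConfig,
    assign_fbh,
    bin_reads,
    filter_hits,
    mask_repeats,
    translated_align,
)

BACK_TABLE = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def back_translate(peptide):
    return "".join(BACK_TABLE[a] for a in peptide)


PEPTIDE_50 = "MKVLITAGHEELLWQRPDNSTKYFMKVAGHEELLWQRPDNSTKYFVVVDE"


class TestMaskRepeats:
    def _repeat(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        return SequenceRecord("rep", "".join(rng.choice(list("ACGT"), n)))

    def test_fully_repetitive_read_removed(self):
        rep = self._repeat()
        read = SequenceRecord("r", rep.seq[:200])
        assert mask_repeats([read], [rep]) == []

    def test_long_clean_flanks_survive(self):
        rep = self._repeat(1)
        rng = np.random.default_rng(2)
        left = "".join(rng.choice(list("ACGT"), 120))
        right = "".join(rng.choice(list("ACGT"), 130))
        read = SequenceRecord("r", left + rep.seq[:50] + right)
        out = mask_repeats([read], [rep])
        assert len(out) == 1
        assert len(out[0].seq) >= 100  # the longest repeat-free run is kept

    def test_99bp_clean_run_removed(self):
        rep = self._repeat(3)
        rng = np.random.default_rng(4)
        clean = "".join(rng.choice(list("ACGT"), 99))
        read = SequenceRecord("r", rep.seq[:51] + clean)
        assert mask_repeats([read], [rep]) == []

    def test_reverse_strand_repeats_masked(self):
        rep = self._repeat(5)
        rc = str(Seq(rep.seq).reverse_complement())
        read = SequenceRecord("r", rc[:200])
        assert mask_repeats([read], [rep]) == []

    def test_idempotent(self):
        rep = self._repeat(6)
        rng = np.random.default_rng(7)
        reads = [
            SequenceRecord(
                f"r{i}",
                "".join(rng.choice(list("ACGT"), 150)) + rep.seq[:60]
                + "".join(rng.choice(list("ACGT"), 150)),
            )
            for i in range(5)
        ]
        once = mask_repeats(reads, [rep])
        twice = mask_repeats(once, [rep])
        assert [(r.id, r.seq) for r in once] == [(r.id, r.seq) for r in twice]

    def test_empty_library_passes_through_with_warning(self):
        reads = [SequenceRecord("r", "ACGT" * 50)]
        with pytest.warns(UserWarning):
            assert mask_repeats(reads, []) == reads


class TestTranslatedAlign:
    def test_exact_back_translation_full_identity(self):
        read = SequenceRecord("r", back_translate(PEPTIDE_50))
        hits = translated_align(read, SequenceRecord("p", PEPTIDE_50))
        best = hits[0]
        assert best.frame == 1
        assert best.pct_identity == 100.0
        assert best.aln_len_aa == 50
        assert (best.q_start, best.q_end) == (0, 150)

    def test_reverse_complement_hits_negative_frame(self):
        nt = back_translate(PEPTIDE_50)
        read = SequenceRecord("r", str(Seq(nt).reverse_complement()))
        hits = translated_align(read, SequenceRecord("p", PEPTIDE_50))
        best = hits[0]
        assert best.frame < 0
        assert best.pct_identity == 100.0
        assert best.aln_len_aa == 50

    def test_five_substitutions_give_90pct(self):
        mutated = list(PEPTIDE_50)
        # interior, conservative-ish substitutions so the local alignment
        # spans the full peptide rather than trimming the ends
        for pos, aa in [(5, "A"), (15, "S"), (25, "T"), (35, "N"), (44, "Q")]:
            assert mutated[pos] != aa
            mutated[pos] = aa
        read = SequenceRecord("r", back_translate("".join(mutated)))
        hits = translated_align(read, SequenceRecord("p", PEPTIDE_50))
        best = hits[0]
        assert best.aln_len_aa == 50
        assert best.pct_identity == pytest.approx(90.0)

    def test_too_short_read_rejected(self):
        with pytest.raises(ValueError):
            translated_align(SequenceRecord("r", "AC"), SequenceRecord("p", "MK"))


class TestFilterHits:
    def _hit(self, aln_len, ident, subject="ogr1"):
        return HitTableRow(
            query_id="q", subject_id=subject, pct_identity=ident,
            aln_len_aa=aln_len, q_start=0, q_end=3 * aln_len, s_start=0,
            s_end=aln_len, frame=1, score=50,
        )

    def test_29aa_rejected_even_at_full_identity(self):
        cfg = BinningConfig()
        assert filter_hits([self._hit(29, 100.0)], cfg) == []

    def test_length_and_identity_thresholds_inclusive(self):
        cfg = BinningConfig(identity_threshold={"default": 70.0})
        kept = filter_hits([self._hit(30, 70.0)], cfg)
        assert len(kept) == 1

    def test_identity_just_below_threshold_rejected(self):
        cfg = BinningConfig(identity_threshold={"default": 70.0})
        assert filter_hits([self._hit(45, 69.9)], cfg) == []

    def test_per_species_thresholds(self):
        cfg = BinningConfig(identity_threshold={"brachy": 75.0, "rice": 70.0})
        species = {"ogr1": "brachy", "ogr2": "rice"}
        hits = [self._hit(40, 72.0, "ogr1"), self._hit(40, 72.0, "ogr2")]
        kept = filter_hits(hits, cfg, species)
        assert [h.subject_id for h in kept] == ["ogr2"]

    def test_unknown_species_without_default_rejected(self):
        cfg = BinningConfig(identity_threshold={"brachy": 75.0})
        with pytest.raises(KeyError):
            filter_hits([self._hit(40, 90.0, "mystery")], cfg, {"mystery": "rye"})


class TestAssignFbh:
    def _hit(self, subject, score, aln_len=40):
        return HitTableRow(
            query_id="q", subject_id=subject, pct_identity=90.0,
            aln_len_aa=aln_len, q_start=0, q_end=120, s_start=0, s_end=40,
            frame=1, score=score,
        )

    def test_best_score_wins(self):
        bins = assign_fbh({"r1": [self._hit("OGR1", 80), self._hit("OGR2", 75)]})
        assert len(bins) == 1 and bins[0].ogr_id == "OGR1"

    def test_full_tie_goes_to_lexicographic_smaller(self):
        bins = assign_fbh({"r1": [self._hit("OGRb", 80), self._hit("OGRa", 80)]})
        assert bins[0].ogr_id == "OGRa"

    def test_hitless_read_stays_unbinned(self):
        assert assign_fbh({"r1": []}) == []

    def test_bins_partition_assigned_reads(self):
        per_read = {
            f"r{i}": [self._hit(f"OGR{i % 3}", 50 + i)] for i in range(12)
        }
        bins = assign_fbh(per_read)
        all_ids = [r for b in bins for r in b.read_ids]
        assert sorted(all_ids) == sorted(per_read)


class TestEndToEndBinning:
    def test_error_free_reads_bin_to_source_gene(self, small_gene_space):
        """>=99% of error-free coding reads land in their own family's bin."""
        from polygenespace.simdata import (
            SimConfig, simulate_reads, transcripts_from_gene_space,
        )

        chromosome, genes, _ = small_gene_space
        transcripts = transcripts_from_gene_space(chromosome, genes)
        templates = [SequenceRecord(t.id, t.seq) for t in transcripts]
        reads = simulate_reads(templates, SimConfig(error_rate=0.0, seed=17))
        ogrs = [SequenceRecord(g.family_id, g.protein) for g in genes]
        fam_of_gene = {g.gene_id: g.family_id for g in genes}
        bins, _ = bin_reads(reads, ogrs, [])
        n_ok = n_assigned = 0
        for b in bins:
            for rid in b.read_ids:
                n_assigned += 1
                source_gene = rid.split("|")[1]
                if fam_of_gene[source_gene] == b.ogr_id:
                    n_ok += 1
        assert n_assigned > 0
        assert n_ok / n_assigned >= 0.99
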