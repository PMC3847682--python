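import numpy as np
import pytest

from polygenespace.io_formats import MarkerRecord, SequenceRecord
from polygenespace.simdata import generate_gene_space, mutate, transcripts_from_gene_space
from polygenespace.zipper import (
    SyntenyBlock,
    anchor_markers,
    anchor_ngs,
    build_zipper,
    detect_synteny,
)


@pytest.fixture(scope="module")
def reference_world():
    """An ordered reference gene set plus diverged query transcripts."""
    chrom, genes, _ = generate_gene_space(30, repeat_fraction=0, seed=21)
    transcripts = transcripts_from_gene_space(chrom, genes)
    ref = [SequenceRecord(f"r{i:02d}", g.protein) for i, g in enumerate(genes)]
    rng = np.random.default_rng(22)
    queries = [
        SequenceRecord(f"q{i:02d}", mutate(t.seq, 0.02, rng))
        for i, t in enumerate(transcripts)
    ]
    return ref, queries, transcripts


class TestDetectSynteny:
    def test_dense_hits_merge_into_block(self, reference_world):
        ref, queries, _ = reference_world
        blocks = detect_synteny(queries, ref, window=5, min_density=3)
        assert len(blocks) == 1
        assert (blocks[0].start_index, blocks[0].end_index) == (0, len(ref) - 1)
        assert blocks[0].support == len(ref)

    def test_sparse_hits_give_no_block(self, reference_world):
        ref, queries, _ = reference_world
        blocks = detect_synteny(queries[::10], ref, window=5, min_density=3)
        assert blocks == []

    def test_window_density_rule(self, reference_world):
        """4 hit genes inside one 5-gene window qualify at density 3."""
        ref, queries, _ = reference_world
        subset = [queries[i] for i in (10, 11, 12, 14)]
        blocks = detect_synteny(subset, ref, window=5, min_density=3)
        assert len(blocks) == 1
        assert blocks[0].start_index >= 10 and blocks[0].end_index <= 14

    def test_identity_threshold_excludes_weak_hits(self, reference_world):
        ref, queries, _ = reference_world
        blocks = detect_synteny(queries, ref, identity_min=99.9, window=5, min_density=3)
        assert blocks == []

    def test_duplicate_reference_ids_rejected(self, reference_world):
        ref, queries, _ = reference_world
        with pytest.raises(ValueError):
            detect_synteny(queries, [ref[0], ref[0]])


class TestAnchorMarkers:
    def test_reciprocal_best_anchored(self, reference_world):
        ref, _, transcripts = reference_world
        markers = []
        for cm, gi in [(10.0, 2), (20.0, 10), (30.0, 20)]:
            t = transcripts[gi]
            s, _ = t.coding[0]
            markers.append(MarkerRecord(f"m{gi}", "1H", cm, t.seq[s : s + 150]))
        anchors = anchor_markers(markers, ref)
        assert anchors == {"m2": 2, "m10": 10, "m20": 20}

    def test_hitless_marker_unanchored(self, reference_world):
        ref, _, _ = reference_world
        rng = np.random.default_rng(23)
        markers = [MarkerRecord("mX", "1H", 5.0, "".join(rng.choice(list("ACGT"), 150)))]
        assert anchor_markers(markers, ref) == {}

    def test_non_reciprocal_marker_unanchored(self, reference_world):
        """Two markers from the same gene: only the better one keeps the
        gene; the other fails reciprocity."""
        ref, _, transcripts = reference_world
        t = transcripts[5]
        s, e = t.coding[0]
        good = MarkerRecord("m_good", "1H", 1.0, t.seq[s : s + 240])
        rng = np.random.default_rng(24)
        weak_seq = mutate(t.seq[s : s + 150], 0.05, rng)
        weak = MarkerRecord("m_weak", "1H", 2.0, weak_seq)
        anchors = anchor_markers([good, weak], ref)
        assert anchors.get("m_good") == 5
        assert "m_weak" not in anchors


class TestBuildZipper:
    def _setup(self, reference_world, marker_genes, cms=None):
        ref, queries, transcripts = reference_world
        cms = cms or [10.0 * (i + 1) for i in range(len(marker_genes))]
        markers = []
        for cm, gi in zip(cms, marker_genes):
            t = transcripts[gi]
            s, _ = t.coding[0]
            markers.append(MarkerRecord(f"m{gi}", "1H", cm, t.seq[s : s + 150]))
        blocks = [SyntenyBlock("ref", 0, len(ref) - 1, support=len(ref))]
        anchors = {f"m{gi}": gi for gi in marker_genes}
        return ref, queries, markers, {"ref": anchors}, {"ref": blocks}

    def test_interval_projection_in_reference_order(self, reference_world):
        ref, queries, markers, anchors, blocks = self._setup(reference_world, [5, 9])
        res = build_zipper(markers, anchors, blocks, {"ref": ref}, ["ref"])
        genes = [r.ref_gene_ids.get("ref") for r in res.rows]
        assert genes == ["r05", "r06", "r07", "r08", "r09"]

    def test_inverted_interval_flagged_and_reversed(self, reference_world):
        ref, queries, markers, anchors, blocks = self._setup(reference_world, [9, 5])
        res = build_zipper(markers, anchors, blocks, {"ref": ref}, ["ref"])
        genes = [r.ref_gene_ids.get("ref") for r in res.rows]
        assert genes == ["r09", "r08", "r07", "r06", "r05"]
        assert all(r.inverted for r in res.rows if r.marker_id is None)

    def test_marker_order_preserved(self, reference_world):
        ref, queries, markers, anchors, blocks = self._setup(
            reference_world, [2, 12, 22], cms=[5.0, 15.0, 40.0]
        )
        res = build_zipper(markers, anchors, blocks, {"ref": ref}, ["ref"])
        marker_rows = [(r.marker_id, r.cm) for r in res.rows if r.marker_id]
        assert marker_rows == [("m2", 5.0), ("m12", 15.0), ("m22", 40.0)]

    def test_ngs_anchored_once_and_unplaced_reported(self, reference_world):
        ref, queries, markers, anchors, blocks = self._setup(reference_world, [2, 27])
        ngs_anchors = {"ref": anchor_ngs(queries, ref)}
        res = build_zipper(markers, anchors, blocks, {"ref": ref}, ["ref"], ngs_anchors)
        placed = [n for r in res.rows for n in r.anchored_ngs_ids]
        assert len(placed) == len(set(placed))
        assert set(placed) | set(res.unplaced_ngs) == set(ngs_anchors["ref"])
        # each gene id appears at most once in the reference column
        genes = [r.ref_gene_ids["ref"] for r in res.rows if "ref" in r.ref_gene_ids]
        assert len(genes) == len(set(genes))

    def test_lower_rank_fills_missing_anchor(self, reference_world):
        """When the top-ranked reference lacks one anchor, the interval
        falls through to the next-ranked reference."""
        ref, queries, markers, anchors, blocks = self._setup(reference_world, [5, 9])
        top_anchors = {"m5": 5}  # second marker missing on the top reference
        res = build_zipper(
            markers,
            {"top": top_anchors, "ref": anchors["ref"]},
            {"top": blocks["ref"], "ref": blocks["ref"]},
            {"top": ref, "ref": ref},
            ["top", "ref"],
        )
        genes = [r.ref_gene_ids.get("ref") for r in res.rows if r.marker_id is None]
        assert genes == ["r06", "r07", "r08"]


class TestOrderRecovery:
    def test_shuffled_reference_order_mostly_recovered(self, reference_world):
        """With a locally shuffled reference (~10% adjacent swaps) and a
        marker backbone, >=90% of placed-gene pairwise order relations
        match the true order, and marker order is exact."""
        ref, queries, transcripts = reference_world
        true_index = {r.id: i for i, r in enumerate(ref)}
        rng = np.random.default_rng(25)
        shuffled = list(ref)
        for i in range(0, len(shuffled) - 1, 2):
            if rng.random() < 0.2:  # ~10% of genes take part in a swap
                shuffled[i], shuffled[i + 1] = shuffled[i + 1], shuffled[i]
        order_on_ref = {r.id: i for i, r in enumerate(shuffled)}
        marker_genes = [0, 7, 15, 23, 29]
        markers = []
        for cm, gi in zip([10.0, 20.0, 30.0, 40.0, 50.0], marker_genes):
            t = transcripts[gi]
            s, _ = t.coding[0]
            markers.append(MarkerRecord(f"m{gi}", "1H", cm, t.seq[s : s + 150]))
        anchors = {
            f"m{gi}": order_on_ref[f"r{gi:02d}"] for gi in marker_genes
        }
        blocks = [SyntenyBlock("ref", 0, len(shuffled) - 1, support=len(shuffled))]
        res = build_zipper(
            markers, {"ref": anchors}, {"ref": blocks}, {"ref": shuffled}, ["ref"]
        )
        placed = [r.ref_gene_ids["ref"] for r in res.rows if "ref" in r.ref_gene_ids]
        concordant = total = 0
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                total += 1
                if true_index[placed[i]] < true_index[placed[j]]:
                    concordant += 1
        assert total > 0
        assert concordant / total >= 0.9
        marker_cms = [r.cm for r in res.rows if r.marker_id]
        assert marker_cms == sorted(marker_cms)
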