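import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Seq import Seq

from polygenespace.io_formats import SequenceRecord
from polygenespace.simdata import SimConfig, simulate_reads
from polygenespace.subassembly import (
    AssemblyConfig,
    assemble_bin,
    assembly_sweep,
    find_overlaps,
)


def tile_reads(template, read_len, step, prefix="r", strand_rng=None):
    """Error-free reads tiling a template at fixed step."""
    reads = []
    i = 0
    for start in range(0, max(len(template) - read_len + 1, 1), step):
        frag = template[start : start + read_len]
        if strand_rng is not None and strand_rng.random() < 0.5:
            frag = str(Seq(frag).reverse_complement())
        reads.append(SequenceRecord(f"{prefix}{i:03d}", frag))
        i += 1
    return reads


def random_template(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


class TestFindOverlaps:
    def test_exact_50bp_overlap_found(self):
        t = random_template(350, 0)
        reads = [SequenceRecord("a", t[:200]), SequenceRecord("b", t[150:350])]
        cfg = AssemblyConfig(mi=99.0, min_overlap_bp=40)
        ovs = find_overlaps(reads, cfg)
        assert len(ovs) == 1
        assert ovs[0].length == 50 and ovs[0].identity == 100.0

    def test_one_mismatch_in_50bp_respects_mi(self):
        """49/50 matching columns = 98.0%: below mi=99, above mi=97."""
        t = random_template(350, 1)
        b_seq = list(t[150:350])
        b_seq[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b_seq[25]]
        reads = [SequenceRecord("a", t[:200]), SequenceRecord("b", "".join(b_seq))]
        assert find_overlaps(reads, AssemblyConfig(mi=99.0)) == []
        ovs = find_overlaps(reads, AssemblyConfig(mi=97.0))
        assert len(ovs) == 1
        assert ovs[0].identity == pytest.approx(98.0)

    def test_reverse_strand_overlap(self):
        t = random_template(300, 2)
        rc = str(Seq(t[100:300]).reverse_complement())
        reads = [SequenceRecord("a", t[:200]), SequenceRecord("b", rc)]
        ovs = find_overlaps(reads, AssemblyConfig(mi=99.0))
        assert len(ovs) == 1 and ovs[0].strand == -1


class TestAssembleBin:
    def test_perfect_tiling_reconstructs_template(self):
        t = random_template(1000, 3)
        reads = tile_reads(t, 200, 40)
        cfg = AssemblyConfig(mi=100.0, correct_errors=False)
        subs, stats = assemble_bin(reads, cfg)
        contigs = [s for s in subs if s.kind == "contig"]
        assert len(contigs) == 1
        assert contigs[0].seq in (t, str(Seq(t).reverse_complement()))
        assert stats.n_assembled == len(reads)
        assert stats.n_singleton == stats.n_excluded == 0

    def test_single_read_becomes_singleton(self):
        subs, stats = assemble_bin([SequenceRecord("r", random_template(300, 4))])
        assert len(subs) == 1 and subs[0].kind == "singleton"
        assert stats.n_singleton == 1 and stats.n_assembled == 0

    def test_ultra_short_read_excluded(self):
        reads = [SequenceRecord("r", "ACGTACGT")]
        _, stats = assemble_bin(reads, AssemblyConfig(min_read_bp=50))
        assert stats.n_excluded == 1

    def test_homeolog_copies_separate_at_99_collapse_at_97(self):
        """Two copies diverged by ~1.4% (one substitution every 70 bp):
        every cross-copy overlap sits strictly below 99% (a 300 bp overlap
        holds >= 4 substitutions) but above 97% identity."""
        a = random_template(1200, 5)
        b = list(a)
        for pos in range(40, 1200, 70):
            b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
        b = "".join(b)
        reads = tile_reads(a, 300, 75, "a") + tile_reads(b, 300, 75, "b")
        strict, _ = assemble_bin(reads, AssemblyConfig(mi=99.0, correct_errors=False))
        relaxed, _ = assemble_bin(reads, AssemblyConfig(mi=97.0, correct_errors=False))
        assert len([s for s in strict if s.kind == "contig"]) == 2
        assert len([s for s in relaxed if s.kind == "contig"]) == 1

    def test_read_conservation(self, small_reads):
        """Every input read is assembled, singleton, or excluded."""
        reads = [r for r in small_reads[:60]]
        subs, stats = assemble_bin(reads, AssemblyConfig(mi=99.0))
        assert stats.total == len(reads)
        in_subs = {m for s in subs for m in s.member_reads}
        assert in_subs <= {r.id for r in reads}

    def test_consensus_at_least_as_long_as_longest_member(self):
        t = random_template(800, 6)
        reads = tile_reads(t, 250, 100)
        subs, _ = assemble_bin(reads, AssemblyConfig(mi=100.0, correct_errors=False))
        read_len = {r.id: len(r.seq) for r in reads}
        for s in subs:
            if s.kind == "contig":
                assert len(s.seq) >= max(read_len[m] for m in s.member_reads)


class TestGreedyVsBruteForce:
    """The greedy layout's contig count must match an independent oracle:
    exhaustive all-pairs, all-offsets overlap detection followed by
    connected-component counting."""

    @staticmethod
    def oracle_group_sizes(reads, min_overlap, mi):
        def arr(s):
            return np.frombuffer(s.encode(), dtype="S1")

        g = nx.Graph()
        g.add_nodes_from(r.id for r in reads)
        for x, y in itertools.combinations(reads, 2):
            found = False
            for ys in (y.seq, str(Seq(y.seq).reverse_complement())):
                a, b = arr(x.seq), arr(ys)
                for off in range(-len(b) + min_overlap, len(a) - min_overlap + 1):
                    lo, hi = max(0, off), min(len(a), off + len(b))
                    if hi - lo < min_overlap:
                        continue
                    sa, sb = a[lo:hi], b[lo - off : hi - off]
                    ident = 100.0 * (sa == sb).mean()
                    if ident >= mi:
                        g.add_edge(x.id, y.id)
                        found = True
                        break
                if found:
                    break
        return sorted(len(c) for c in nx.connected_components(g))

    def test_matches_oracle_on_random_small_bins(self):
        rng = np.random.default_rng(123)
        cfg = AssemblyConfig(
            mi=100.0, min_overlap_bp=20, min_contig_bp=1, min_read_bp=20,
            correct_errors=False, depth_excess=1e9,
        )
        n_checked = 0
        for trial in range(60):
            t = random_template(int(rng.integers(150, 300)), 1000 + trial)
            n_reads = int(rng.integers(2, 9))
            reads = []
            for i in range(n_reads):
                length = int(rng.integers(40, 100))
                start = int(rng.integers(0, len(t) - length + 1))
                frag = t[start : start + length]
                if rng.random() < 0.5:
                    frag = str(Seq(frag).reverse_complement())
                reads.append(SequenceRecord(f"t{trial}r{i}", frag))
            subs, _ = assemble_bin(reads, cfg)
            got = sorted(len(s.member_reads) for s in subs)
            expected = self.oracle_group_sizes(reads, 20, 100.0)
            assert got == expected, f"trial {trial}"
            n_checked += 1
        assert n_checked == 60


class TestAssemblySweep:
    def test_error_free_bin_identical_across_mi(self):
        t = random_template(900, 7)
        bins = {"b0": tile_reads(t, 250, 70)}
        table = assembly_sweep(
            bins, base_cfg=AssemblyConfig(correct_errors=False)
        )
        assert table["n_assembled"].nunique() == 1
        assert table["n_singleton"].nunique() == 1

    def test_noisy_reads_assemble_less_at_higher_mi(self):
        t = SequenceRecord("t", random_template(2500, 8))
        cfg = SimConfig(coverage=6, error_rate=0.005, read_len_mean=300,
                        read_len_sd=40, seed=9)
        reads = simulate_reads([t], cfg)
        bins = {"b0": reads}
        table = assembly_sweep(bins, base_cfg=AssemblyConfig(correct_errors=False))
        frac = table["n_assembled"] / (
            table["n_assembled"] + table["n_singleton"] + table["n_excluded"]
        )
        by_mi = dict(zip(table["mi"], frac))
        assert by_mi[100.0] < by_mi[97.0]
        # monotone: non-increasing assembled fraction, non-decreasing singletons
        assert list(frac) == sorted(frac, reverse=True)
        singles = list(table["n_singleton"])
        assert singles == sorted(singles)

    def test_empty_bin_set(self):
        table = assembly_sweep({})
        assert (table["n_assembled"] == 0).all()
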