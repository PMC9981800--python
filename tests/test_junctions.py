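"""Anchor index, mapper vs substring oracle, chimera calling, clustering."""

import numpy as np
import pytest

from ivscan.junctions import (AnchorIndex, ChimericRead, JunctionCluster,
                              call_chimeric, cluster_junctions, filter_support,
                              map_read, map_read_fast)
from ivscan.seqcore import CircularSegment, LinearSequence, revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _oracle_runs(read: str, refs, k: int) -> set[tuple]:
    """Exhaustive substring-search oracle: for every reference and strand,
    every maximal read interval of length >= k that occurs contiguously in
    the (doubled, for circles) reference text."""
    out = set()
    n = len(read)
    for ref in refs:
        circ = ref.topology == "circular"
        text = ref.seq + ref.seq if circ else ref.seq
        for strand in "+-":
            q = read if strand == "+" else revcomp(read)
            s = 0
            while s <= len(q) - k:
                if q[s:s + k] not in text:
                    s += 1
                    continue
                e = s + k
                while e < len(q) and q[s:e + 1] in text:
                    e += 1
                maximal = s == 0 or q[s - 1:e] not in text
                if maximal:
                    rs, re = (s, e) if strand == "+" else (n - e, n - s)
                    out.add((ref.id, strand, rs, re))
                s += 1
    # keep only runs not contained in a longer run on the same ref/strand
    keep = set()
    for r in out:
        rid, st, a, b = r
        if not any(rid == r2[0] and st == r2[1] and r2[2] <= a and b <= r2[3]
                   and (a, b) != (r2[2], r2[3]) for r2 in out):
            keep.add(r)
    return keep


class TestAnchorIndex:
    def test_positions_and_even_k_rejected(self):
        ref = LinearSequence("r", "ACGTACGTA")
        idx = AnchorIndex([ref], k=3)
        code = sum({"A": 0, "C": 1, "G": 2, "T": 3}[c] * 4 ** (2 - i)
                   for i, c in enumerate("ACG"))
        assert sorted(p for _, p in idx.lookup(code)) == [0, 4]
        with pytest.raises(ValueError, match="odd"):
            AnchorIndex([ref], k=4)

    def test_circular_kmer_spanning_origin_indexed(self, rng):
        seq = _rand(rng, 60)
        circ = CircularSegment("c", seq)
        idx = AnchorIndex([circ], k=5)
        wrap = seq[-2:] + seq[:3]  # spans the origin
        runs = map_read(wrap + "", idx) if len(wrap) >= 5 else []
        assert any(r.ref_id == "c" and r.ref_start == 58 for r in runs)

    def test_k_longer_than_shortest_ref_rejected(self):
        with pytest.raises(ValueError, match="shortest"):
            AnchorIndex([LinearSequence("r", "ACGTACG")], k=9)


class TestMapRead:
    def test_exact_substring_single_run(self, rng):
        ref = LinearSequence("r", _rand(rng, 5000))
        idx = AnchorIndex([ref], k=21)
        read = ref.seq[1000:1150]
        (run,) = map_read(read, idx)
        assert (run.read_start, run.read_end) == (0, 150)
        assert (run.ref_start, run.ref_end, run.strand) == (1000, 1150, "+")

    def test_revcomp_read_maps_minus(self, rng):
        ref = LinearSequence("r", _rand(rng, 5000))
        idx = AnchorIndex([ref], k=21)
        (run,) = map_read(revcomp(ref.seq[2000:2150]), idx)
        assert (run.ref_start, run.ref_end, run.strand) == (2000, 2150, "-")

    def test_substitution_splits_into_flanking_runs(self, rng):
        ref = LinearSequence("r", _rand(rng, 5000))
        idx = AnchorIndex([ref], k=21)
        read = list(ref.seq[3000:3150])
        read[70] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[70]]
        runs = [r for r in map_read("".join(read), idx) if r.strand == "+"]
        assert {(r.read_start, r.read_end) for r in runs} == {(0, 70), (71, 150)}

    def test_unrelated_read_maps_nowhere(self, rng):
        ref = LinearSequence("r", _rand(rng, 2000))
        idx = AnchorIndex([ref], k=21)
        rng2 = np.random.default_rng(777)
        assert map_read(_rand(rng2, 150), idx) == []

    @pytest.mark.parametrize("n_subs", [0, 1, 2])
    def test_agrees_with_substring_oracle(self, n_subs):
        rng = np.random.default_rng(4242)
        refs = [LinearSequence("chrA", _rand(rng, 20_000)),
                CircularSegment("segB", _rand(rng, 4000)),
                CircularSegment("segC", _rand(rng, 3000))]
        idx = AnchorIndex(refs, k=21)
        texts = {r.id: (r.seq + r.seq if r.topology == "circular" else r.seq)
                 for r in refs}
        for _ in range(25):
            src = refs[int(rng.integers(0, 3))]
            L = len(src)
            start = int(rng.integers(0, L - 150)) if src.topology == "linear" \
                else int(rng.integers(0, L))
            read = list(texts[src.id][start:start + 150])
            for p in rng.choice(150, size=n_subs, replace=False):
                read[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[p]]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            got = {(r.ref_id, r.strand, r.read_start, r.read_end)
                   for r in map_read(read, idx)}
            assert got == _oracle_runs(read, refs, 21)

    def test_fast_path_equals_full_mapper_on_clean_reads(self, rng):
        refs = [LinearSequence("h", _rand(rng, 8000)),
                CircularSegment("v", _rand(rng, 3000))]
        idx = AnchorIndex(refs, k=21)
        for start in (0, 1234, 7850):
            read = refs[0].seq[start:start + 150]
            if len(read) < 150:
                continue
            assert map_read_fast(read, idx) == map_read(read, idx)


class TestCallChimeric:
    @pytest.fixture
    def chimeric_setup(self, rng):
        host_seq = _rand(rng, 6000)
        viral_seq = _rand(rng, 3000)
        # read: bases 0-80 from host, bases 70-150 from viral (10 bp shared)
        shared = host_seq[1070:1080]
        viral_seq = viral_seq[:500] + shared + viral_seq[510:]
        read = host_seq[1000:1080] + viral_seq[510:590]
        host = LinearSequence("chr1", host_seq)
        viral = CircularSegment("F2", viral_seq)
        return host, viral, read

    def test_constructed_overlap_ten(self, chimeric_setup):
        host, viral, read = chimeric_setup
        idx = AnchorIndex([host, viral], k=21)
        runs = map_read(read, idx)
        chi = call_chimeric("r1", runs, len(read), circle_lengths={"F2": 3000})
        assert chi is not None
        assert chi.segment_id == "F2" and chi.host_chrom == "chr1"
        assert chi.overlap_len == 10
        assert chi.side == "left" and chi.host_breakpoint == 1080

    def test_revcomp_read_same_junction(self, chimeric_setup):
        host, viral, read = chimeric_setup
        idx = AnchorIndex([host, viral], k=21)
        chi_f = call_chimeric("f", map_read(read, idx), len(read),
                              circle_lengths={"F2": 3000})
        chi_r = call_chimeric("r", map_read(revcomp(read), idx), len(read),
                              circle_lengths={"F2": 3000})
        assert (chi_f.side, chi_f.host_breakpoint, chi_f.viral_breakpoint,
                chi_f.overlap_len) == (chi_r.side, chi_r.host_breakpoint,
                                       chi_r.viral_breakpoint, chi_r.overlap_len)

    def test_fully_viral_read_not_chimeric(self, rng):
        viral = CircularSegment("v", _rand(rng, 3000))
        host = LinearSequence("h", _rand(rng, 3000))
        idx = AnchorIndex([host, viral], k=21)
        read = (viral.seq + viral.seq)[100:250]
        assert call_chimeric("r", map_read(read, idx), 150) is None

    def test_short_viral_anchor_rejected(self, chimeric_setup):
        host, viral, read = chimeric_setup
        idx = AnchorIndex([host, viral], k=21)
        # keep only 15 viral bases: below the 25 bp anchor requirement
        short = read[:85]
        runs = map_read(short, idx)
        assert call_chimeric("r", runs, len(short)) is None


class TestClustering:
    def _read(self, i, bp, side="left", seg="F2", chrom="chr1"):
        return ChimericRead(
            read_id=f"r{i}", segment_id=seg, viral_interval=(0, 75),
            viral_strand="+", host_chrom=chrom, host_interval=(bp - 75, bp),
            host_strand="+", read_breakpoint=75, overlap_len=40, side=side,
            host_breakpoint=bp, viral_breakpoint=100, rel_strand="+")

    def test_tight_group_one_cluster(self, rng):
        reads = [self._read(i, 1000 + int(rng.integers(-3, 4)))
                 for i in range(20)]
        (c,) = cluster_junctions(reads, cluster_tol=5)
        assert c.support == 20
        assert abs(c.host_breakpoint - 1000) <= 3

    def test_groups_thirty_bp_apart_split(self):
        reads = [self._read(i, 1000) for i in range(5)]
        reads += [self._read(i + 5, 1030) for i in range(5)]
        cs = cluster_junctions(reads, cluster_tol=5)
        assert len(cs) == 2
        assert sorted(c.host_breakpoint for c in cs) == [1000, 1030]

    def test_single_linkage_chains(self):
        # consecutive gaps of 4 <= tol chain into one cluster even though the
        # extremes are 16 apart
        reads = [self._read(i, 1000 + 4 * i) for i in range(5)]
        (c,) = cluster_junctions(reads, cluster_tol=5)
        assert c.support == 5
        assert c.host_breakpoint == 1008  # median

    def test_sides_and_segments_kept_separate(self):
        reads = [self._read(0, 1000, side="left"),
                 self._read(1, 1000, side="right"),
                 self._read(2, 1000, seg="E3")]
        assert len(cluster_junctions(reads)) == 3

    def test_empty_input(self):
        assert cluster_junctions([]) == []

    def test_order_independence(self, rng):
        reads = [self._read(i, 1000 + int(rng.integers(-3, 4)))
                 for i in range(12)]
        a = cluster_junctions(reads)
        b = cluster_junctions(list(reversed(reads)))
        assert [(c.host_breakpoint, c.support) for c in a] == \
               [(c.host_breakpoint, c.support) for c in b]


class TestFilterSupport:
    def _cluster(self, support):
        return JunctionCluster("F2", "chr1", "left", 100, 50, "+", support,
                               tuple(f"r{i}" for i in range(support)))

    def test_threshold_fifteen(self):
        clusters = [self._cluster(s) for s in (3, 9, 15, 22, 40)]
        kept, removed = filter_support(clusters, min_support=15)
        assert [c.support for c in kept] == [15, 22, 40]
        assert all("support" in why for _, why in removed)

    def test_min_support_one_is_identity(self):
        clusters = [self._cluster(s) for s in (1, 2, 3)]
        kept, removed = filter_support(clusters, min_support=1)
        assert kept == clusters and removed == []

    def test_all_below_threshold_empty_but_ok(self):
        kept, removed = filter_support([self._cluster(2)], min_support=15)
        assert kept == [] and len(removed) == 1
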