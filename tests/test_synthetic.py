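"""Generator: determinism, genome composition, integration geometry, reads."""

import filecmp

import pytest
from Bio.Seq import Seq

from ivscan.seqcore import CircularSegment, LinearSequence, revcomp
from ivscan.synthetic import (DEFAULT_CENSUS, GeneratorConfig, make_host,
                              make_viral_genome, plant_integrations,
                              simulate_dataset, simulate_reads)

from conftest import SMALL_CENSUS


def _tiny_cfg(**kw):
    base = dict(seed=3, n_host_chroms=2, host_chrom_bp=30_000, n_segments=4,
                segment_len_range=(1500, 2500), sites_per_segment=1,
                coverage=5, error_rate=0.0)
    base.update(kw)
    return GeneratorConfig(**base)


class TestHost:
    def test_sizes_and_gc(self):
        cfg = GeneratorConfig(seed=11, n_host_chroms=5, host_chrom_bp=200_000)
        host = make_host(cfg)
        assert sum(len(h) for h in host) == 1_000_000
        gc = sum(h.seq.count("G") + h.seq.count("C") for h in host) / 1_000_000
        assert abs(gc - cfg.host_gc) < 0.01

    def test_deterministic(self):
        cfg = _tiny_cfg()
        h1 = make_host(cfg)
        h2 = make_host(cfg)
        assert [(a.id, a.seq) for a in h1] == [(b.id, b.seq) for b in h2]


class TestViralGenome:
    def test_default_census_counts(self):
        assert sum(DEFAULT_CENSUS.values()) == 123

    def test_segment_count_lengths_and_gene_census(self):
        cfg = GeneratorConfig(seed=5)
        genome, ann = make_viral_genome(cfg)
        assert len(genome) == 62
        lengths = [len(s) for s in genome]
        assert min(lengths) >= 1500 and max(lengths) <= 8200
        assert len(ann) == 123
        gc = sum(s.seq.count("G") + s.seq.count("C") for s in genome)
        assert abs(gc / genome.total_bp - 0.43) < 0.01

    def test_placed_genes_are_stop_free_orfs(self):
        cfg = GeneratorConfig(seed=5)
        genome, ann = make_viral_genome(cfg)
        for a in ann:
            seg = genome[a.segment_id]
            nt = seg.seq[a.start:a.end]
            if a.strand == "-":
                nt = revcomp(nt)
            assert nt.startswith("ATG")
            prot = str(Seq(nt).translate())
            assert prot.endswith("*") and "*" not in prot[:-1]

    def test_barcodes_make_segments_distinguishable(self):
        cfg = _tiny_cfg()
        genome, _ = make_viral_genome(cfg, census=SMALL_CENSUS)
        canon = {s.canonical() for s in genome}
        assert len(canon) == len(genome)

    def test_unplaceable_census_raises(self):
        cfg = _tiny_cfg(n_segments=2, segment_len_range=(1500, 1600))
        with pytest.raises(ValueError, match="without overlap"):
            make_viral_genome(cfg, census={"hypothetical": 50})


@pytest.fixture(scope="module")
def planted():
    cfg = _tiny_cfg(sites_per_segment=2, integrated_segment_ids=None)
    host = make_host(cfg)
    viral, _ = make_viral_genome(cfg, census=SMALL_CENSUS)
    href, vref, para, truth = plant_integrations(host, viral, cfg)
    return cfg, host, viral, href, vref, para, truth


class TestPlantIntegrations:

    def test_length_bookkeeping(self, planted):
        cfg, host, viral, href, vref, para, truth = planted
        # host reference gains one arm per event; parasitized locus grows by
        # the full (arm-bearing) segment relative to the host reference
        for chrom in host:
            h0 = len(chrom)
            events = [t for t in truth if t.host_chrom == chrom.id]
            href_len = len(next(h for h in href if h.id == chrom.id))
            para_len = len(next(h for h in para if h.id == chrom.id))
            assert href_len == h0 + sum(t.arm_len for t in events)
            assert para_len == href_len + sum(len(vref[t.segment_id])
                                              for t in events)

    def test_arm_present_in_both_references(self, planted):
        cfg, host, viral, href, vref, para, truth = planted
        for t in truth:
            chrom = next(h for h in href if h.id == t.host_chrom)
            assert chrom.seq[t.arm_start:t.arm_start + t.arm_len] == t.arm_seq
            circ = vref[t.segment_id]
            doubled = circ.seq + circ.seq
            expected = t.arm_seq if t.orientation == "+" else revcomp(t.arm_seq)
            assert doubled[t.viral_breakpoint:
                           t.viral_breakpoint + t.arm_len] == expected

    def test_reconstruction_oracle_excision_restores_host(self, planted):
        cfg, host, viral, href, vref, para, truth = planted
        # removing each inserted circle (one arm copy plus the opened circle)
        # from the parasitized chromosome restores the host reference exactly
        for chrom in href:
            events = sorted((t for t in truth if t.host_chrom == chrom.id),
                            key=lambda t: t.arm_start)
            p = next(h for h in para if h.id == chrom.id).seq
            offset = 0
            for t in events:
                seg_len = len(vref[t.segment_id])
                start = t.arm_start + offset
                block = p[start:start + seg_len + t.arm_len]
                assert block.startswith(t.arm_seq) and block.endswith(t.arm_seq)
                p = p[:start] + p[start + seg_len:]
                # one arm copy survives the excision at the original locus
                assert p[start:start + t.arm_len] == t.arm_seq
            assert p == chrom.seq

    def test_flank_guard_blocks_chance_extension(self, planted):
        cfg, host, viral, href, vref, para, truth = planted
        for t in truth:
            chrom = next(h for h in href if h.id == t.host_chrom).seq
            circ = vref[t.segment_id]
            if t.orientation == "+":
                oriented, q = circ.seq, t.viral_breakpoint
            else:
                oriented = revcomp(circ.seq)
                q = len(circ) - t.viral_breakpoint - t.arm_len
            assert chrom[t.arm_start - 1] != oriented[q - 1]
            assert chrom[t.arm_start + t.arm_len] != oriented[(q + t.arm_len)
                                                              % len(circ)]

    def test_zero_events_leaves_host_untouched(self):
        cfg = _tiny_cfg(integrated_segment_ids=(), sites_per_segment=0)
        host = make_host(cfg)
        viral, _ = make_viral_genome(cfg, census=SMALL_CENSUS)
        href, vref, para, truth = plant_integrations(host, viral, cfg)
        assert truth == []
        assert [(h.id, h.seq) for h in para] == [(h.id, h.seq) for h in host]
        assert [(s.id, s.seq) for s in vref] == [(s.id, s.seq) for s in viral]

    def test_arm_lengths_span_default_range(self, many_events_detect):
        _, _, truth, _ = many_events_detect
        arm_lens = [t.arm_len for t in truth]
        assert len(arm_lens) >= 200
        assert min(arm_lens) == 36 and max(arm_lens) == 46


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, tmp_path, rng):
        cfg = _tiny_cfg(coverage=3)
        refs = [LinearSequence("l1", "".join(rng.choice(list("ACGT"), 4000))),
                CircularSegment("c1", "".join(rng.choice(list("ACGT"), 2000)))]
        n = simulate_reads(refs, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        texts = {r.id: (r.seq + r.seq if r.topology == "circular" else r.seq)
                 for r in refs}
        import pysam
        n_seen = 0
        with pysam.FastxFile(str(tmp_path / "r1.fq")) as f1, \
                pysam.FastxFile(str(tmp_path / "r2.fq")) as f2:
            for e1, e2 in zip(f1, f2):
                n_seen += 1
                hit = any(e1.sequence in t or revcomp(e1.sequence) in t
                          for t in texts.values())
                hit2 = any(e2.sequence in t or revcomp(e2.sequence) in t
                           for t in texts.values())
                assert hit and hit2
        assert n_seen == n

    def test_pair_count_formula(self, tmp_path, rng):
        cfg = _tiny_cfg(coverage=30)
        refs = [LinearSequence("l", "".join(rng.choice(list("ACGT"), 100_000)))]
        n = simulate_reads(refs, cfg, tmp_path / "a.fq", tmp_path / "b.fq")
        assert n == round(30 * 100_000 / (2 * 150)) == 10_000

    def test_zero_coverage_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            _tiny_cfg(coverage=0).validate()


class TestDatasetDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = _tiny_cfg()
        p1 = simulate_dataset(cfg, tmp_path / "run1", census=SMALL_CENSUS)
        p2 = simulate_dataset(cfg, tmp_path / "run2", census=SMALL_CENSUS)
        for key in ("host", "viral", "parasitized", "r1", "r2", "truth",
                    "truth_bed", "annotation"):
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_truth_rows_consistent_with_emitted_fasta(self, small_sim):
        from ivscan.seqcore import read_fasta
        from ivscan.synthetic import read_truth
        cfg, paths = small_sim
        host = {h.id: h.seq for h in read_fasta(paths["host"], "linear")}
        truth = read_truth(paths["truth"])
        assert truth
        for t in truth:
            assert host[t.host_chrom][t.arm_start:
                                      t.arm_start + t.arm_len] == t.arm_seq
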