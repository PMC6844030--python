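"""Synthetic genome pair, read simulation and mixture design."""

import math

import numpy as np
import pytest

from xenopurity import simdata
from xenopurity.samutils import fastq_read_ids
from xenopurity.simdata import MixtureSpec, design_benchmark, make_genome_pair, make_mixture


class TestGenomePair:
    def test_zero_divergence_is_identity(self, zero_divergence_pair):
        pair = zero_divergence_pair
        assert pair.truth_sites == []
        for contig in pair.shared_contigs:
            assert pair.host_sequences[contig] == pair.contaminant_sequences[contig]

    def test_deterministic_for_fixed_seed(self):
        a = make_genome_pair(1, 10_000, 0.01, 0.1, 0.001, seed=7)
        b = make_genome_pair(1, 10_000, 0.01, 0.1, 0.001, seed=7)
        assert a.host_sequences == b.host_sequences
        assert a.contaminant_sequences == b.contaminant_sequences
        assert a.truth_sites == b.truth_sites

    def test_site_counts_match_binomial_expectation(self):
        pair = make_genome_pair(1, 100_000, 0.01, 0.1, 0.001, seed=7)
        snvs = [s for s in pair.truth_sites if s.kind == "snv"]
        n, p = 100_000, 0.01
        sd = math.sqrt(n * p * (1 - p))
        assert abs(len(snvs) - n * p) < 4 * sd
        n_het = sum(s.zygosity == "het" for s in pair.truth_sites)
        m = len(pair.truth_sites)
        sd_het = math.sqrt(m * 0.1 * 0.9)
        assert abs(n_het - 0.1 * m) < 4 * sd_het

    def test_truth_site_invariants(self, pair):
        keys = [(s.contig, s.pos) for s in pair.truth_sites]
        assert len(keys) == len(set(keys)), "sites must be unique per (contig, pos)"
        for s in pair.truth_sites:
            assert 1 <= s.pos <= len(pair.host_sequences[s.contig])
            ref_in_genome = pair.host_sequences[s.contig][s.pos - 1 : s.pos - 1 + len(s.ref)]
            assert ref_in_genome == s.ref
            if s.kind == "snv":
                assert s.alt != s.ref

    def test_divergent_sites_only_at_truth_positions(self):
        pair = make_genome_pair(1, 5_000, 0.005, 0.0, 0.0, seed=5,
                                contaminant_only_fraction=0.0)
        host = pair.host_sequences["chr1"]
        cont = pair.contaminant_sequences["chr1"]
        diff = {i + 1 for i in range(len(host)) if host[i] != cont[i]}
        assert diff == {s.pos for s in pair.truth_sites}

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            make_genome_pair(1, 500)  # too short
        with pytest.raises(ValueError):
            make_genome_pair(1, 10_000, divergence_rate=1.5)


class TestSimulateReads:
    def test_read_count_tracks_depth(self, pair, tmp_path):
        targets = [("chr1", 0, 10_000)]
        fq1, fq2 = simdata.simulate_reads(
            "host", pair, targets, mean_depth=50, read_length=100,
            seed=1, out_prefix=tmp_path / "h")
        n = len(fastq_read_ids(fq1))
        assert abs(n - 2_500) <= 250  # depth*span/(2*read_length) +- 10%
        assert len(fastq_read_ids(fq2)) == n

    def test_origin_tag_round_trip(self, pair, tmp_path):
        fq1, _ = simdata.simulate_reads(
            "contaminant", pair, [("chr1", 0, 2_000)], mean_depth=5,
            seed=1, out_prefix=tmp_path / "c")
        ids = fastq_read_ids(fq1)
        assert ids and all(simdata.parse_origin(r) == "contaminant" for r in ids)
        assert simdata.parse_origin("plain_read_name") == "unknown"

    def test_empty_targets_rejected(self, pair, tmp_path):
        with pytest.raises(ValueError):
            simdata.simulate_reads("host", pair, [], 30, out_prefix=tmp_path / "x")

    def test_deterministic_per_seed(self, pair, tmp_path):
        import gzip

        args = dict(mean_depth=10, seed=42)
        a, _ = simdata.simulate_reads("host", pair, [("chr1", 0, 3000)],
                                      out_prefix=tmp_path / "a", **args)
        b, _ = simdata.simulate_reads("host", pair, [("chr1", 0, 3000)],
                                      out_prefix=tmp_path / "b", **args)
        assert gzip.open(a).read() == gzip.open(b).read()


class TestBenchmarkDesign:
    def test_canonical_design_yields_150_mixtures(self):
        specs = design_benchmark(
            ["h1", "h2"], ["m1", "m2", "m3", "m4", "m5"],
            list(simdata.CANONICAL_RATES), n_seeds=3)
        assert len(specs) == 150
        assert len({s.seed for s in specs}) == 150

    def test_complementary_downsampling(self):
        # 80% contamination leaves a 20% host fraction
        spec = MixtureSpec.build("h", "m", 0.8, seed=0, total_reads=10_000)
        assert spec.n_mouse_reads == 8_000
        assert spec.n_human_reads == 2_000

    def test_equal_split_at_half(self):
        (spec,) = design_benchmark(["h"], ["m"], [0.5], 1)
        assert spec.n_mouse_reads == spec.n_human_reads

    @pytest.mark.parametrize("rate,total", [(0.05, 4000), (0.1, 10_000), (0.33, 999)])
    def test_read_count_invariant(self, rate, total):
        spec = MixtureSpec.build("h", "m", rate, seed=1, total_reads=total)
        assert spec.n_mouse_reads == round(total * rate)
        assert spec.n_mouse_reads + spec.n_human_reads == total

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            design_benchmark(["h", "h"], ["m"], [0.5], 1)
        with pytest.raises(ValueError):
            design_benchmark(["h"], ["m"], [1.5], 1)


@pytest.fixture(scope="module")
def source_fastqs(pair, tmp_path_factory):
    wd = tmp_path_factory.mktemp("mix_sources")
    host = simdata.simulate_reads("host", pair, [("chr1", 0, 20_000)],
                                  mean_depth=30, seed=5, out_prefix=wd / "h")
    cont = simdata.simulate_reads("contaminant", pair, [("chr1", 0, 20_000)],
                                  mean_depth=30, seed=6, out_prefix=wd / "m")
    return host, cont


class TestMakeMixture:
    def test_origin_proportions_exact(self, source_fastqs, tmp_path):
        host, cont = source_fastqs
        spec = MixtureSpec.build("h", "m", 0.2, seed=9, total_reads=5_000)
        fq1, fq2 = make_mixture(spec, host, cont, tmp_path / "mix")
        origins = [simdata.parse_origin(r) for r in fastq_read_ids(fq1)]
        # counts are fragment-level; each FASTQ holds one mate per fragment
        assert origins.count("contaminant") == spec.n_mouse_reads // 2
        assert origins.count("host") == spec.n_human_reads // 2
        assert fastq_read_ids(fq1) == fastq_read_ids(fq2)

    def test_rate_zero_is_pure_host_downsample(self, source_fastqs, tmp_path):
        host, cont = source_fastqs
        spec = MixtureSpec.build("h", "m", 0.0, seed=9, total_reads=1_000)
        fq1, _ = make_mixture(spec, host, cont, tmp_path / "pure")
        ids = fastq_read_ids(fq1)
        assert len(ids) == 500
        assert all(simdata.parse_origin(r) == "host" for r in ids)
        assert set(ids) <= set(fastq_read_ids(host[0]))

    def test_deterministic_per_seed(self, source_fastqs, tmp_path):
        host, cont = source_fastqs
        spec = MixtureSpec.build("h", "m", 0.5, seed=21, total_reads=2_000)
        a, _ = make_mixture(spec, host, cont, tmp_path / "a")
        b, _ = make_mixture(spec, host, cont, tmp_path / "b")
        assert set(fastq_read_ids(a)) == set(fastq_read_ids(b))

    def test_insufficient_reads_reports_deficit(self, source_fastqs, tmp_path):
        host, cont = source_fastqs
        spec = MixtureSpec.build("h", "m", 0.5, seed=1, total_reads=10_000_000)
        with pytest.raises(ValueError, match="deficit"):
            make_mixture(spec, host, cont, tmp_path / "big")


def test_mixture_alignment_matches_fastq_sampling(study):
    """The pre-aligned-subset route samples exactly the fragments the FASTQ
    mixer samples for the same spec and seed."""
    from xenopurity import workflows
    from xenopurity.samutils import primary_read_ids

    spec = study["spec"]
    out = study["workdir"] / "resampled.bam"
    workflows.mixture_alignment(spec, study["host_query"], study["mouse_query"], out)
    assert primary_read_ids(out) == set(fastq_read_ids(study["fastq"][0]))
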