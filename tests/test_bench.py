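"""Benchmark metrics: confusion counts, H_f reduction, callable sites, RPKM."""

import numpy as np
import pandas as pd
import pytest

from xenopurity import bench
from xenopurity.bench import (ConfusionCounts, Metrics, count_callable_hamas,
                              hf_reduction, mean_metrics, rpkm_per_gene,
                              score_filter)
from xenopurity.filters import FilterOutcome
from xenopurity.pileup import AllelicCount


def _outcome(removed, retained):
    return FilterOutcome(retained_ids=set(retained), removed_ids=set(removed), method="t")


class TestScoreFilter:
    def test_tabulated_confusion_arithmetic(self):
        m = Metrics.from_counts(ConfusionCounts(tp=90, fn=10, tn=95, fp=5))
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.95)
        assert m.precision == pytest.approx(90 / 95)
        assert m.accuracy == pytest.approx(185 / 200)
        assert m.f_score == pytest.approx(2 * 0.90 * 0.95 / 1.85)

    def test_perfect_filter(self):
        labels = {"c1": "contaminant", "c2": "contaminant", "h1": "host"}
        m = score_filter(_outcome({"c1", "c2"}, {"h1"}), labels)
        assert (m.sensitivity, m.specificity, m.f_score) == (1.0, 1.0, 1.0)

    def test_remove_nothing(self):
        labels = {"c1": "contaminant", "h1": "host"}
        m = score_filter(_outcome(set(), {"c1", "h1"}), labels)
        assert (m.sensitivity, m.specificity) == (0.0, 1.0)

    def test_unknown_origin_raises_unless_ignored(self):
        labels = {"a": "host"}
        with pytest.raises(ValueError, match="unknown origin"):
            score_filter(_outcome(set(), {"a", "b"}), labels)
        m = score_filter(_outcome(set(), {"a", "b"}), labels, ignore_unknown=True)
        assert m.counts.total == 1

    def test_f_score_symmetric_in_sens_and_spec(self):
        # counts chosen so (sens, spec) = (0.9, 0.6) and the mirror (0.6, 0.9)
        a = Metrics.from_counts(ConfusionCounts(tp=90, fn=10, tn=60, fp=40))
        b = Metrics.from_counts(ConfusionCounts(tp=60, fn=40, tn=90, fp=10))
        assert a.f_score == pytest.approx(b.f_score)
        # harmonic mean is bounded by min and max
        assert min(a.sensitivity, a.specificity) <= a.f_score <= max(a.sensitivity, a.specificity)

    def test_totals_conserved_across_methods(self, study):
        from xenopurity.filters import concatref_filter, dualref_lenient, dualref_strict

        labels = study["origin_labels"]
        metrics = [
            score_filter(concatref_filter(study["bam_concat"], study["origin_map"]), labels),
            score_filter(dualref_strict(study["bam_host"], study["bam_contaminant"]), labels),
            score_filter(dualref_lenient(study["bam_host"], study["bam_contaminant"]), labels),
        ]
        totals = {m.counts.total for m in metrics}
        contaminant_totals = {m.counts.tp + m.counts.fn for m in metrics}
        assert len(totals) == 1 and len(contaminant_totals) == 1

    def test_mean_metrics_over_replicates(self):
        ms = [Metrics.from_counts(ConfusionCounts(tp=9, fn=1, tn=9, fp=1)),
              Metrics.from_counts(ConfusionCounts(tp=7, fn=3, tn=10, fp=0))]
        agg = mean_metrics(ms)
        assert agg["sensitivity"] == pytest.approx((0.9 + 0.7) / 2)
        assert agg["specificity"] == pytest.approx((0.9 + 1.0) / 2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fn=0, tn=0, fp=0)


def _ac(pos, ref_count, alt_counts, contig="chr1", ref_base="G"):
    return AllelicCount(contig=contig, pos=pos, ref_base=ref_base,
                        ref_count=ref_count, alt_counts=dict(alt_counts))


CATALOG = pd.DataFrame({
    "contig": ["chr1", "chr1"], "pos": [10, 20],
    "ref": ["G", "G"], "alt": ["A", "A"],
})


class TestHfReduction:
    def test_identical_pileups_give_zero(self):
        counts = {(r.contig, r.pos): _ac(r.pos, 10, {"A": 5}) for r in CATALOG.itertuples()}
        total, per_site = hf_reduction(counts, counts, CATALOG)
        assert total == 0.0
        assert (per_site["reduction"] == 0).all()

    def test_tabulated_reduction(self):
        before = {("chr1", 10): _ac(10, 6, {"A": 4}),   # hf 0.40
                  ("chr1", 20): _ac(20, 8, {"A": 2})}   # hf 0.20
        after = {("chr1", 10): _ac(10, 9, {"A": 1}),    # hf 0.10
                 ("chr1", 20): _ac(20, 8, {"A": 2})}    # hf 0.20
        total, per_site = hf_reduction(before, after, CATALOG)
        assert total == pytest.approx(0.30)
        assert per_site["reduction"].tolist() == pytest.approx([0.30, 0.0])

    def test_perfect_filter_zeroes_hama_allele(self):
        before = {("chr1", 10): _ac(10, 5, {"A": 5}), ("chr1", 20): _ac(20, 5, {"A": 5})}
        after = {("chr1", 10): _ac(10, 5, {}), ("chr1", 20): _ac(20, 5, {})}
        _, per_site = hf_reduction(before, after, CATALOG)
        assert (per_site["hf_after"] == 0).all()


class TestCallableHamas:
    def test_strict_boundaries(self):
        # VAF exactly at the threshold is NOT callable; alt count exactly 5 is NOT
        counts = {("chr1", 10): _ac(10, 95, {"A": 5}),   # vaf 0.05, alt 5
                  ("chr1", 20): _ac(20, 80, {"A": 20})}  # vaf 0.20, alt 20
        assert count_callable_hamas(counts, CATALOG) == 1

    def test_matches_brute_force_on_random_pileups(self):
        rng = np.random.default_rng(42)
        catalog = pd.DataFrame({
            "contig": "chr1", "pos": np.arange(1, 101),
            "ref": "G", "alt": "A",
        })
        counts = {}
        for pos in catalog["pos"]:
            depth = int(rng.integers(0, 60))
            alt = int(rng.integers(0, depth + 1))
            counts[("chr1", int(pos))] = _ac(int(pos), depth - alt, {"A": alt} if alt else {})
        for min_vaf, min_alt in [(0.05, 5), (0.2, 3), (0.5, 5), (0.0, 0)]:
            expected = 0
            for pos in catalog["pos"]:
                ac = counts[("chr1", int(pos))]
                alt = ac.alt_counts.get("A", 0)
                if alt > min_alt and ac.depth > 0 and alt / ac.depth > min_vaf:
                    expected += 1
            assert count_callable_hamas(counts, catalog, min_vaf, min_alt) == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(7)
        catalog = pd.DataFrame({"contig": "chr1", "pos": np.arange(1, 51),
                                "ref": "G", "alt": "A"})
        counts = {("chr1", int(p)): _ac(int(p), int(rng.integers(0, 40)),
                                        {"A": int(rng.integers(0, 20))})
                  for p in catalog["pos"]}
        by_vaf = [count_callable_hamas(counts, catalog, v, 5) for v in (0.0, 0.05, 0.2, 0.5)]
        by_alt = [count_callable_hamas(counts, catalog, 0.05, a) for a in (0, 5, 10, 15)]
        assert by_vaf == sorted(by_vaf, reverse=True)
        assert by_alt == sorted(by_alt, reverse=True)


class TestRpkm:
    GENES = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"], "contig": "chr1",
        "start": [0, 5000, 9000], "end": [2000, 6000, 10000],
    })

    def test_arithmetic_example(self):
        df = rpkm_per_gene({"g1": 1000}, self.GENES, total_mapped=1_000_000)
        assert df.set_index("gene_id").loc["g1", "rpkm"] == pytest.approx(500.0)

    def test_zero_reads_not_sensitive(self):
        df = rpkm_per_gene({}, self.GENES, total_mapped=1_000_000)
        assert (df["rpkm"] == 0).all()
        assert not df["sensitive"].any()

    def test_threshold_is_strict(self):
        # 2 kb gene, 1M mapped: 80 reads -> RPKM exactly 40 -> not sensitive
        df = rpkm_per_gene({"g1": 80, "g2": 41}, self.GENES, total_mapped=1_000_000)
        out = df.set_index("gene_id")
        assert out.loc["g1", "rpkm"] == pytest.approx(40.0)
        assert not out.loc["g1", "sensitive"]
        assert out.loc["g2", "rpkm"] == pytest.approx(41.0)  # 1 kb gene
        assert bool(out.loc["g2", "sensitive"])

    def test_gene_counting_from_alignment(self, study):
        genes = pd.DataFrame({"gene_id": ["win1", "win2"], "contig": "chr1",
                              "start": [0, 15_000], "end": [5_000, 20_000]})
        counts = bench.count_reads_per_gene(study["bam_host"], genes)
        assert set(counts) == {"win1", "win2"}
        assert all(v > 0 for v in counts.values())
        df = rpkm_per_gene(counts, genes, total_mapped=6000)
        assert (df["rpkm"] > 0).all()
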