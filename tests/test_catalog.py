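"""HAMA catalog: pileup calling, intersection, zygosity, H_f/H_c, risk."""

import pysam
import pytest

from xenopurity import catalog as cat
from xenopurity import simdata, workflows
from xenopurity.catalog import VariantCall
from xenopurity.samutils import sort_index


def _toy_bam(tmp_path, ref_seq, reads):
    """Write a tiny BAM of gapless 20 bp reads: list of (pos0, seq)."""
    header = pysam.AlignmentHeader.from_references(["chr1"], [len(ref_seq)])
    unsorted = tmp_path / "toy_unsorted.bam"
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        for i, (pos, seq) in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{i:04d}"
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    return sort_index(unsorted, tmp_path / "toy.bam")


REF = ("ACGTACGTACGTACGTACGT" * 5)  # 100 bp


class TestPileupCaller:
    def test_unanimous_alt_called_homozygous(self, tmp_path):
        alt_read = "A" + REF[11:30]  # covers pos0 10..29, alt A at pos0 10 (ref G)
        assert REF[10] == "G"
        bam = _toy_bam(tmp_path, REF, [(10, alt_read)] * 30)
        calls = cat.call_contaminant_alleles(bam, {"chr1": REF})
        assert len(calls) == 1
        c = calls[0]
        assert (c.contig, c.pos, c.ref, c.alt, c.zygosity, c.kind) == (
            "chr1", 11, "G", "A", "hom", "snv")

    def test_half_alt_called_heterozygous(self, tmp_path):
        alt_read = "A" + REF[11:30]
        ref_read = REF[10:30]
        bam = _toy_bam(tmp_path, REF, [(10, alt_read)] * 15 + [(10, ref_read)] * 15)
        calls = cat.call_contaminant_alleles(bam, {"chr1": REF})
        assert [c.zygosity for c in calls] == ["het"]
        assert calls[0].vaf == pytest.approx(0.5)

    def test_below_het_threshold_not_called(self, tmp_path):
        alt_read = "A" + REF[11:30]
        ref_read = REF[10:30]
        bam = _toy_bam(tmp_path, REF, [(10, alt_read)] * 3 + [(10, ref_read)] * 27)
        assert cat.call_contaminant_alleles(bam, {"chr1": REF}) == []

    def test_zero_divergence_yields_empty_catalog(self, zero_divergence_pair, tmp_path):
        sample = workflows.simulate_and_align(
            zero_divergence_pair, "contaminant", [("chr1", 0, 5_000)],
            mean_depth=20, seed=8, sample_id="m0", workdir=tmp_path,
            error_rate=0.0)
        assert cat.call_contaminant_alleles(sample.bam,
                                            zero_divergence_pair.host_sequences) == []


class TestIntersection:
    def _call(self, pos, alt="A", zyg="hom"):
        return VariantCall("chr1", pos, "G", alt, "snv", zyg, 1.0, 30)

    def test_common_requires_presence_in_all_samples(self):
        five = [[self._call(10)] for _ in range(5)]
        common, _ = cat.intersect_common(five)
        assert common == [("chr1", 10, "G", "A")]
        four_of_five = [[self._call(10)] for _ in range(4)] + [[]]
        common, _ = cat.intersect_common(four_of_five)
        assert common == []

    def test_specific_sets_are_singletons(self):
        lists = [[self._call(10), self._call(20)], [self._call(10)], [self._call(10)]]
        _, specific = cat.intersect_common(lists)
        assert specific[0] == {("chr1", 20, "G", "A")}
        assert specific[1] == specific[2] == set()

    def test_common_set_shrinks_with_more_samples(self):
        lists = [[self._call(p) for p in range(1, 30 - 3 * i)] for i in range(5)]
        sizes = [len(cat.intersect_common(lists[:k])[0]) for k in range(2, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            cat.intersect_common([[self._call(10)]])


class TestZygosityRule:
    def test_any_het_makes_site_het(self):
        lists = [[self._c("hom")] for _ in range(4)] + [[self._c("het")]]
        assert cat.classify_zygosity(lists, ("chr1", 10, "G", "A")) == "het"

    def test_all_hom_stays_hom(self):
        lists = [[self._c("hom")] for _ in range(5)]
        assert cat.classify_zygosity(lists, ("chr1", 10, "G", "A")) == "hom"

    def test_all_het_stays_het(self):
        lists = [[self._c("het")] for _ in range(5)]
        assert cat.classify_zygosity(lists, ("chr1", 10, "G", "A")) == "het"

    @staticmethod
    def _c(zyg):
        return VariantCall("chr1", 10, "G", "A", "snv", zyg, 0.5, 30)


class TestHfHc:
    def test_hf_arithmetic(self):
        site = ("chr1", 100)
        assert cat.compute_hf(site, {site: 50}, {site: 50}) == pytest.approx(0.5)
        assert cat.compute_hf(site, {site: 0}, {site: 80}) == 0.0
        assert cat.compute_hf(site, {site: 30}, {site: 90}) == pytest.approx(0.25)

    def test_hf_error_cases(self):
        site = ("chr1", 100)
        with pytest.raises(KeyError):
            cat.compute_hf(site, {}, {site: 10})
        with pytest.raises(ValueError):
            cat.compute_hf(site, {site: 0}, {site: 0})

    def test_hc_examples(self):
        assert cat.compute_hc(0.05, 0.05) == pytest.approx(1.0)
        assert cat.compute_hc(0.10, 0.05) == pytest.approx(2.0)
        assert cat.compute_hc(0.0, 0.3) == 0.0
        with pytest.raises(ValueError):
            cat.compute_hc(0.1, 0.0)

    @pytest.mark.parametrize("h_f,alpha", [(0.05, 0.05), (0.37, 0.2), (0.0, 0.8), (1.0, 1.0)])
    def test_hc_round_trip_exact(self, h_f, alpha):
        assert cat.compute_hc(h_f, alpha) * alpha == h_f

    def test_risk_boundary(self):
        assert cat.classify_risk(1.0) == "high"
        assert cat.classify_risk(0.999) == "low"
        assert cat.classify_risk(3.0) == "high"


class TestSyntheticCatalog:
    def test_catalog_alleles_are_true_divergent_sites(self, study):
        """After left-normalization (catalog indels are pileup-anchored,
        truth sites left-normalized) every catalog allele is a truth site."""
        from xenopurity.variants import normalize_variant

        ref = study["pair"].host_sequences
        truth_keys = {s.key for s in study["pair"].truth_sites}
        catalog_keys = {
            normalize_variant(r.contig, int(r.pos), r.ref, r.alt, ref)
            for r in study["catalog"].itertuples()
        }
        assert catalog_keys, "catalog must not be empty"
        assert catalog_keys <= truth_keys

    def test_well_covered_hom_snvs_are_recovered(self, study):
        syn = study["synthetic"]
        pair = study["pair"]
        catalog_keys = {
            (r.contig, r.pos, r.ref, r.alt) for r in study["catalog"].itertuples()
        }
        from xenopurity.samutils import mean_depth_table

        hom_snvs = [s for s in pair.truth_sites if s.zygosity == "hom" and s.kind == "snv"]
        depths = mean_depth_table([m.bam for m in syn.mouse_samples],
                                  [(s.contig, s.pos) for s in hom_snvs])
        covered = [s for s in hom_snvs if depths[(s.contig, s.pos)] >= 15]
        assert covered
        recovered = sum(s.key in catalog_keys for s in covered)
        assert recovered / len(covered) >= 0.95

    def test_het_sites_show_half_allele_fraction(self, study):
        """Contaminant reads emit either allele at het sites with prob 1/2."""
        from xenopurity import pileup

        syn = study["synthetic"]
        df = study["catalog"]
        hets = df[(df.zygosity == "het") & (df.kind == "snv")]
        assert len(hets) >= 5
        sites = [(r.contig, int(r.pos)) for r in hets.itertuples()]
        counts = pileup.count_at_sites(syn.mouse_samples[0].bam,
                                       study["pair"].host_sequences, sites)
        fracs = []
        for r in hets.itertuples():
            ac = counts[(r.contig, int(r.pos))]
            if ac.depth >= 15:
                fracs.append(ac.allele_fraction(pileup.allele_key(r.ref, r.alt)))
        mean = sum(fracs) / len(fracs)
        assert abs(mean - 0.5) < 4 * (0.5 / (len(fracs) * 15) ** 0.5)

    def test_catalog_round_trips_through_tsv(self, study, tmp_path):
        path = cat.write_catalog(study["catalog"], tmp_path / "hama.tsv")
        df = cat.read_catalog(path)
        assert len(df) == len(study["catalog"])
        assert list(df.columns) == cat.CATALOG_COLUMNS
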