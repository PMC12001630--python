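"""Variant hard filters, intragenic annotation and 3' positional bias."""

import numpy as np
import pytest

from satdepth import (
    FilterThresholds,
    GeneModel,
    SimVariantParams,
    VariantRecord,
    classify_intragenic,
    filter_lenient,
    filter_stringent,
    known_site_overlap,
    position_histogram,
    read_gene_models,
    read_vcf,
    relative_position,
    simulate_gene_models,
    simulate_variant_records,
    site_hard_filter,
    write_gff3,
    write_vcf,
)
from satdepth._errors import ParameterError
from satdepth.variants import SampleCall, is_snp, thin_variant_depths

PASSING_INFO = {"QD": 25.0, "FS": 5.0, "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "SOR": 2.0}


def record(pos=100, info=None, samples=((8, 2, 10),), chrom="chr1", ref="A", alts=("C",)):
    """Record helper; samples are (ad_ref, ad_alt, dp) triples."""
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=list(alts),
        site_info=dict(PASSING_INFO if info is None else info),
        per_sample=[SampleCall(ad=[r, a], dp=d) for r, a, d in samples],
    )


class TestSiteHardFilter:
    def test_all_passing(self):
        passed, labels = site_hard_filter(record())
        assert passed and labels == []

    @pytest.mark.parametrize(
        "key,value",
        [("QD", 19.9), ("FS", 20.5), ("MQRankSum", -12.6),
         ("ReadPosRankSum", -8.1), ("SOR", 5.1)],
    )
    def test_each_violation_fails_with_label(self, key, value):
        info = dict(PASSING_INFO, **{key: value})
        passed, labels = site_hard_filter(record(info=info))
        assert not passed and labels == [key]

    @pytest.mark.parametrize(
        "key,value",
        [("QD", 20.0), ("FS", 20.0), ("MQRankSum", -12.5),
         ("ReadPosRankSum", -8.0), ("SOR", 5.0)],
    )
    def test_exact_threshold_passes(self, key, value):
        # the filters are strict inequalities (QD < 20 fails; QD = 20 passes)
        info = dict(PASSING_INFO, **{key: value})
        passed, _ = site_hard_filter(record(info=info))
        assert passed

    def test_missing_annotations_pass_flagged(self):
        passed, labels = site_hard_filter(record(info={}))
        assert passed and labels == ["unannotated"]


class TestLenient:
    def test_depth_spread_over_samples(self):
        rec = record(samples=((4, 0, 4), (3, 1, 4), (4, 0, 4)))
        kept, _ = filter_lenient([rec])
        assert kept == [rec]  # DP_total 12 >= 10, ALT_AD_total 1 > 0

    def test_depth_boundary(self):
        below = record(samples=((8, 1, 9),))
        at = record(samples=((8, 1, 10),))
        kept, _ = filter_lenient([below, at])
        assert kept == [at]

    def test_no_alt_support(self):
        rec = record(samples=((50, 0, 50),))
        kept, _ = filter_lenient([rec])
        assert kept == []

    def test_unevaluable_counted(self):
        rec = VariantRecord(
            chrom="chr1", pos=1, ref="A", alts=["C"],
            per_sample=[SampleCall(ad=None, dp=None)],
        )
        kept, unevaluable = filter_lenient([rec])
        assert kept == [] and unevaluable == 1


class TestStringent:
    def test_ad_branch(self):
        rec = record(samples=((98, 2, 100),))
        assert len(filter_stringent([rec])) == 1

    def test_ar_branch_requires_deep_sample(self):
        # AR = 0.125 but DP <= 10: neither branch fires
        rec = record(samples=((7, 1, 8),))
        assert filter_stringent([rec]) == []

    def test_weak_support_spread_over_samples(self):
        # 1 alt read in each of 5 samples at DP 12 (AR 0.083): dropped despite
        # recalculated depth 60
        rec = record(samples=tuple((11, 1, 12) for _ in range(5)))
        assert filter_stringent([rec]) == []

    def test_recalculated_depth_gate(self):
        # supported allele but AD-sum depth below 5
        rec = record(samples=((1, 2, 12),))
        assert filter_stringent([rec]) == []
        rec2 = record(samples=((3, 2, 12),))
        assert len(filter_stringent([rec2])) == 1

    def test_dp_sum_strategy(self):
        rec = record(samples=((1, 2, 12),))
        thresholds = FilterThresholds(recalc_strategy="dp_sum")
        assert len(filter_stringent([rec], thresholds)) == 1

    def test_multiallelic_per_allele(self):
        rec = VariantRecord(
            chrom="chr1", pos=5, ref="A", alts=["C", "G"],
            site_info=dict(PASSING_INFO),
            per_sample=[SampleCall(ad=[10, 3, 1], dp=14)],
        )
        survivors = filter_stringent([rec])
        assert [a for _r, a in survivors] == [0]  # only the first alt supported

    def test_stringent_subset_of_lenient_on_random_fixtures(self):
        genes = simulate_gene_models(seed=5)
        records = simulate_variant_records(
            SimVariantParams(n_variants=500, seed=5), genes
        )
        lenient_keys = {r.key() for r in filter_lenient(records)[0]}
        stringent_keys = {r.key() for r, _a in filter_stringent(records)}
        assert stringent_keys <= lenient_keys


class TestIntragenic:
    GENES = [
        GeneModel("gA", "chr1", 100, 200, "+"),
        GeneModel("gB", "chr1", 150, 400, "-"),  # overlaps gA
        GeneModel("gC", "chr2", 100, 200, "+"),
    ]

    @pytest.mark.parametrize(
        "pos,expected",
        [(100, ["gA"]), (99, []), (201, ["gB"]), (401, []), (175, ["gA", "gB"])],
    )
    def test_inclusive_boundaries_and_nesting(self, pos, expected):
        (result,) = classify_intragenic([record(pos=pos)], self.GENES)
        assert result["intragenic"] is bool(expected)
        assert sorted(result["gene_ids"]) == expected

    def test_chromosome_must_match(self):
        (result,) = classify_intragenic([record(pos=150, chrom="chr3")], self.GENES)
        assert not result["intragenic"]


class TestRelativePosition:
    def test_plus_strand_three_prime_end(self):
        gene = GeneModel("g", "chr1", 100, 200, "+")
        assert relative_position(record(pos=200), gene) == 1.0
        assert relative_position(record(pos=100), gene) == 0.0
        assert relative_position(record(pos=150), gene) == 0.5

    def test_minus_strand_reflection(self):
        gene = GeneModel("g", "chr1", 100, 200, "-")
        assert relative_position(record(pos=100), gene) == 1.0
        assert relative_position(record(pos=200), gene) == 0.0

    def test_single_base_gene(self):
        gene = GeneModel("g", "chr1", 100, 100, "+")
        assert relative_position(record(pos=100), gene) == 0.0

    def test_outside_gene_raises(self):
        gene = GeneModel("g", "chr1", 100, 200, "+")
        with pytest.raises(ParameterError):
            relative_position(record(pos=300), gene)

    def test_strand_reflection_histogram_invariance(self, rng):
        """Mirroring strand and positions leaves the histogram unchanged."""
        plus = GeneModel("g", "chr1", 1000, 2000, "+")
        minus = GeneModel("g", "chr1", 1000, 2000, "-")
        positions = rng.integers(1000, 2001, size=500)
        r_plus = [relative_position(record(pos=int(p)), plus) for p in positions]
        mirrored = [3000 - int(p) for p in positions]
        r_minus = [relative_position(record(pos=p), minus) for p in mirrored]
        assert np.array_equal(
            position_histogram(r_plus, 20), position_histogram(r_minus, 20)
        )


class TestPositionHistogram:
    def test_all_at_three_prime(self):
        hist = position_histogram([1.0] * 7, n_bins=10)
        assert hist[-1] == 7 and hist.sum() == 7

    def test_uniform_values_within_three_sigma(self, rng):
        n, bins = 10_000, 20
        hist = position_histogram(rng.random(n), n_bins=bins)
        expected = n / bins
        sigma = np.sqrt(n * (1 / bins) * (1 - 1 / bins))
        assert (np.abs(hist - expected) < 3 * sigma).all()

    def test_empty_input(self):
        assert position_histogram([], 5).sum() == 0

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            position_histogram([0.5, 1.2])


class TestKnownOverlap:
    def test_identity_and_disjoint(self):
        called = [("chr1", 1, "A", "C"), ("chr1", 2, "G", "T")]
        assert known_site_overlap(called, called)["fraction_known"] == 1.0
        assert known_site_overlap(called, [("chr2", 9, "A", "T")])["fraction_known"] == 0.0

    def test_partial_overlap_fixture(self):
        called = [(f"chr1", i, "A", "C") for i in range(1, 7)]
        known = [(f"chr1", i, "A", "C") for i in range(1, 5)] + [("chr9", 1, "A", "C")]
        result = known_site_overlap(called, known)
        assert result["n_known"] == 4 and result["n_novel"] == 2
        assert result["fraction_known"] == pytest.approx(4 / 6)
        assert result["n_known"] + result["n_novel"] == result["n_called"]

    def test_allele_aware_vs_position_mode(self):
        called = [("chr1", 10, "A", "C")]
        known = [("chr1", 10, "A", "T")]
        assert known_site_overlap(called, known)["n_known"] == 0
        assert known_site_overlap(called, known, mode="position")["n_known"] == 1

    def test_malformed_known_entries_skipped(self):
        called = [("chr1", 10, "A", "C")]
        assert known_site_overlap(called, [("chr1", 10)])["n_known"] == 0


class TestIO:
    def test_vcf_round_trip(self, tmp_path):
        genes = simulate_gene_models(n_genes=10, seed=3)
        records = simulate_variant_records(
            SimVariantParams(n_variants=40, n_samples=3, seed=3), genes
        )
        path = tmp_path / "test.vcf"
        write_vcf(records, path)
        back = read_vcf(path)
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert a.key() == b.key()
            assert a.site_info.keys() == b.site_info.keys()
            for k in a.site_info:
                assert a.site_info[k] == pytest.approx(b.site_info[k], abs=1e-4)
            assert [c.ad for c in a.per_sample] == [c.ad for c in b.per_sample]
            assert [c.dp for c in a.per_sample] == [c.dp for c in b.per_sample]

    def test_gff3_round_trip(self, tmp_path):
        genes = simulate_gene_models(n_genes=8, seed=1)
        path = tmp_path / "genes.gff3"
        write_gff3(genes, path)
        assert read_gene_models(path) == genes


class TestThinning:
    def test_ratio_one_is_identity(self):
        rec = record(samples=((30, 10, 45),))
        (thinned,) = thin_variant_depths([rec], 1.0, seed=0)
        assert [c.ad for c in thinned.per_sample] == [[30, 10]]
        assert thinned.per_sample[0].dp == 45

    def test_ratio_zero_empties(self):
        rec = record(samples=((30, 10, 45),))
        (thinned,) = thin_variant_depths([rec], 0.0, seed=0)
        assert thinned.per_sample[0].ad == [0, 0]
        assert thinned.per_sample[0].dp == 0

    def test_expectation(self, rng):
        rec = record(samples=((200, 100, 300),))
        alt = np.array(
            [
                thin_variant_depths([rec], 0.5, seed=s)[0].per_sample[0].ad[1]
                for s in range(1000)
            ]
        )
        se = np.sqrt(100 * 0.5 * 0.5 / 1000)
        assert abs(alt.mean() - 50.0) < 3 * se


def test_snp_indel_classification():
    assert is_snp(record())
    assert not is_snp(record(ref="AT", alts=("A",)))
    assert not is_snp(record(ref="A", alts=("AT",)))
    multi = VariantRecord(chrom="chr1", pos=1, ref="A", alts=["C", "CT"])
    assert not is_snp(multi)
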