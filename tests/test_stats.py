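"""Raw and calibrated statistics, resampling machinery, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amdr.datatypes import (
    GenotypeDataset,
    InteractionSpec,
    NullCalibration,
    PredisposingTable,
)
from amdr.stats import (
    analyze_all,
    analyze_interaction,
    confidence_interval,
    corrected_statistic,
    ecdf,
    fdr_adjust,
    jackknife_alt,
    permutation_null,
    permutation_pvalue,
    quantile,
    raw_statistics,
)

from _oracles import (
    brute_bh,
    brute_corrected,
    brute_ecdf,
    brute_permutation_null,
    brute_pvalue,
    brute_quantile,
)


def _table(n11, n12, n21, n22):
    return PredisposingTable(
        n11=n11, n12=n12, n21=n21, n22=n22, p0=0.5,
        high_risk=np.array([True, False]),
    )


class TestRawStatistics:
    def test_hand_values(self):
        odds, rr, chi = raw_statistics(_table(20, 10, 10, 20))
        assert odds == pytest.approx(4.0)
        assert rr == pytest.approx(2.0)
        assert chi == pytest.approx(100 / 15)

    def test_symmetric_table(self):
        odds, rr, chi = raw_statistics(_table(15, 15, 15, 15))
        assert (odds, rr, chi) == (1.0, 1.0, 0.0)

    def test_zero_cell_continuity_correction(self):
        odds, rr, _ = raw_statistics(_table(20, 0, 10, 20))
        assert odds == pytest.approx((20.5 * 20.5) / (0.5 * 10.5))
        assert rr == pytest.approx((20.5 / 21) / (10.5 / 31))

    def test_empty_margin_gives_zero_chi(self):
        _, _, chi = raw_statistics(_table(0, 0, 30, 30))
        assert chi == 0.0


class TestEcdfQuantile:
    def test_hand_values(self):
        samples = np.array([1.0, 2.0, 3.0, 4.0])
        assert ecdf(samples, 2.5) == 0.5
        assert quantile(samples, 0.5) == 2.0
        assert ecdf(samples, samples.max()) == 1.0
        assert quantile(samples, 1.0) == samples.max()

    def test_quantile_is_inf_of_upper_level_set(self):
        samples = np.arange(1, 101, dtype=float)
        assert quantile(samples, 0.025) == 3.0
        assert quantile(samples, 0.975) == 98.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.floats(-60, 60),
    )
    def test_mutual_consistency(self, samples, x):
        s = np.asarray(samples)
        p = ecdf(s, x)
        if p > 0:
            assert quantile(s, p) <= x
        assert brute_ecdf(samples, x) == p

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.floats(0, 1),
    )
    def test_quantile_matches_brute(self, samples, p):
        assert quantile(np.asarray(samples), p) == brute_quantile(samples, p)


class TestCorrectedStatistic:
    def test_identity_when_alt_equals_null(self):
        samples = np.array([0.5, 0.8, 1.0, 1.3, 2.0])
        calib = NullCalibration("OR", samples, samples.copy())
        for x in samples:
            assert corrected_statistic(float(x), calib) == 1.0

    def test_above_all_null_uses_max(self):
        calib = NullCalibration("OR", np.array([1.0, 2.0, 4.0]), np.array([5.0]))
        assert corrected_statistic(10.0, calib) == pytest.approx(10.0 / 4.0)

    def test_zero_quantile_clamped_to_smallest_positive(self):
        calib = NullCalibration(
            "Chi", np.array([0.0, 0.0, 0.5, 2.0]), np.array([1.0, 2.0, 3.0, 4.0])
        )
        # rank of 0.9 in alt = 0 -> null minimum 0 -> clamp to 0.5
        assert corrected_statistic(0.9, calib) == pytest.approx(0.9 / 0.5)


class TestPermutationPvalue:
    def test_hand_values(self):
        assert permutation_pvalue(5.0, np.array([1.0, 2.0, 3.0, 6.0])) == 0.25
        assert permutation_pvalue(7.0, np.array([1.0, 2.0])) == 0.0
        assert permutation_pvalue(0.5, np.array([1.0, 2.0])) == 1.0

    def test_conservative_variant_never_zero(self):
        assert permutation_pvalue(9.0, np.array([1.0]), conservative=True) == 0.5


class TestConfidenceInterval:
    def test_integer_resamples(self):
        low, high = confidence_interval(np.arange(1, 101, dtype=float))
        assert (low, high) == (3.0, 98.0)

    def test_constant_resamples(self):
        low, high = confidence_interval(np.full(50, 2.5))
        assert (low, high) == (2.5, 2.5)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-10, 10), min_size=40, max_size=80))
    def test_ordered(self, z):
        low, high = confidence_interval(np.asarray(z))
        assert low <= high


class TestFdr:
    def test_hand_bh(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
    def test_matches_brute_bh_and_dominates_p(self, ps):
        adj = fdr_adjust(ps)
        np.testing.assert_allclose(adj, brute_bh(ps), atol=1e-12)
        assert (adj >= np.asarray(ps) - 1e-12).all()


class TestResampling:
    def test_null_or_median_moderately_inflated(self, null_dataset):
        # the data-driven high/low split inflates the raw OR above 1 even
        # with no association; the calibration step exists to undo this
        null = permutation_null(null_dataset, InteractionSpec((0, 1)), B=1000,
                                rng_seed=0)
        assert 1.0 <= np.median(null["OR"]) < 2.5

    def test_single_permutation(self, null_dataset):
        null = permutation_null(null_dataset, InteractionSpec((0, 1)), B=1,
                                rng_seed=0)
        assert null["OR"].shape == (1,)

    def test_seed_determinism(self, null_dataset):
        spec = InteractionSpec((0, 1))
        a = permutation_null(null_dataset, spec, B=25, rng_seed=42)
        b = permutation_null(null_dataset, spec, B=25, rng_seed=42)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])
        ja = jackknife_alt(null_dataset, spec, B_j=20, rng_seed=42)
        jb = jackknife_alt(null_dataset, spec, B_j=20, rng_seed=42)
        np.testing.assert_array_equal(ja["RR"], jb["RR"])

    def test_signal_separates_alt_from_null(self, xor_dataset):
        spec = InteractionSpec((0, 1))
        null = permutation_null(xor_dataset, spec, B=200, rng_seed=1)
        alt = jackknife_alt(xor_dataset, spec, B_j=100, rng_seed=1)
        assert np.median(alt["Chi"]) > np.quantile(null["Chi"], 0.99)

    def test_jackknife_rejects_bad_fraction(self, null_dataset):
        with pytest.raises(ValueError):
            jackknife_alt(null_dataset, InteractionSpec((0, 1)), fraction=1.5)


class TestBruteForceAgreement:
    """Loop-based recomputation matches the vectorized pipeline exactly."""

    def test_null_samples_bitwise(self):
        rng = np.random.default_rng(31)
        genotypes = rng.integers(0, 3, size=(30, 4)).astype(np.int8)
        phenotype = np.array([1] * 14 + [0] * 16, dtype=np.int8)
        data = GenotypeDataset(genotypes=genotypes, phenotype=phenotype)
        spec = InteractionSpec((1, 3))
        impl = permutation_null(data, spec, B=50, rng_seed=99)
        brute = brute_permutation_null(genotypes, phenotype, spec.loci, 50, 99)
        np.testing.assert_array_equal(impl["OR"], brute["OR"])
        np.testing.assert_array_equal(impl["RR"], brute["RR"])
        np.testing.assert_allclose(impl["Chi"], brute["Chi"], rtol=1e-12)

    def test_corrected_statistic_and_pvalue(self):
        rng = np.random.default_rng(5)
        null = rng.gamma(2.0, 1.0, size=50)
        alt = rng.gamma(3.0, 1.0, size=40)
        calib = NullCalibration("OR", null, alt)
        for x in (0.5, 1.7, 9.0):
            assert corrected_statistic(x, calib) == brute_corrected(x, null, alt)
            assert permutation_pvalue(x, null) == brute_pvalue(x, null)


class TestAnalyzeAll:
    def test_result_count_and_ordering(self, null_dataset):
        results = analyze_all(null_dataset, 2, B=100, B_j=40, rng_seed=0)
        assert len(results) == 6  # C(4, 2)
        pvals = [r.pvalue for r in results]
        assert pvals == sorted(pvals)

    def test_fdr_dominates_pvalue(self, null_dataset):
        results = analyze_all(null_dataset, 2, B=100, B_j=40, rng_seed=0)
        for r in results:
            for name in ("OR", "RR", "Chi"):
                assert r.fdrs[name] >= r.pvalues[name] - 1e-12

    def test_null_data_rarely_significant(self, null_dataset):
        results = analyze_all(null_dataset, 2, B=400, B_j=40, rng_seed=8)
        frac = np.mean([r.pvalue < 0.05 for r in results])
        assert frac <= 0.34  # 6 tests; expect ~5% under the null

    def test_snp_columns_outside_spec_irrelevant(self, null_dataset):
        spec = InteractionSpec((0, 1))
        swapped = GenotypeDataset(
            genotypes=null_dataset.genotypes[:, [0, 1, 3, 2]],
            phenotype=null_dataset.phenotype,
        )
        a = analyze_interaction(null_dataset, spec, B=50, B_j=20, rng_seed=3)
        b = analyze_interaction(swapped, spec, B=50, B_j=20, rng_seed=3)
        assert a.pvalues == b.pvalues
        assert a.corrected == b.corrected

    def test_strong_signal_yields_large_corrected_or(self, xor_dataset):
        res = analyze_interaction(
            xor_dataset, InteractionSpec((0, 1)), B=300, B_j=60, rng_seed=0
        )
        assert res.corrected["OR"] > 1.0
        assert res.pvalues["OR"] == 0.0
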