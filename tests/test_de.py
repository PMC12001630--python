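"""Negative-binomial differential-expression stage."""

import numpy as np
import pytest

from satdepth import (
    CountMatrix,
    adjust_and_call,
    estimate_dispersions,
    nb_wald_test,
    run_de,
    size_factors,
)
from satdepth._errors import DesignError


def matrix_from(counts):
    counts = np.asarray(counts)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
    )


def nb_matrix(rng, mu, n1, n2, alpha=0.1, lfc_ln=0.0):
    """Two-group NB counts; second group's mean multiplied by exp(lfc_ln)."""
    size = 1.0 / alpha
    mu = np.asarray(mu, dtype=float)
    m1 = np.repeat(mu[:, None], n1, axis=1)
    m2 = np.repeat((mu * np.exp(lfc_ln))[:, None], n2, axis=1)
    mus = np.concatenate([m1, m2], axis=1)
    counts = rng.negative_binomial(size, size / (size + mus))
    return matrix_from(counts), ["a"] * n1 + ["b"] * n2


class TestSizeFactors:
    def test_identical_samples(self):
        m = matrix_from(np.array([[5, 5], [9, 9], [2, 2]]))
        assert size_factors(m) == pytest.approx([1.0, 1.0])

    def test_doubled_sample(self):
        m = matrix_from(np.array([[4, 8], [10, 20], [6, 12]]))
        factors = size_factors(m)
        assert factors == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_single_gene_ratio(self):
        m = matrix_from(np.array([[4, 16]]))
        assert size_factors(m) == pytest.approx([0.5, 2.0])

    def test_sparse_fallback(self):
        # no gene is nonzero in every sample; positive-only variant engages
        m = matrix_from(np.array([[4, 0], [0, 9], [8, 0], [0, 18]]))
        factors = size_factors(m)
        assert np.prod(factors) == pytest.approx(1.0)
        with pytest.raises(DesignError):
            size_factors(m, fallback_positive_only=False)


class TestDispersions:
    def test_poisson_data_near_zero(self, rng):
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 300))
        counts = rng.poisson(np.repeat(mu[:, None], 40, axis=1))
        m = matrix_from(counts)
        labels = ["a"] * 20 + ["b"] * 20
        disp = estimate_dispersions(m, np.ones(40), labels)
        assert np.median(disp) <= 0.01

    def test_nb_data_recovers_alpha(self, rng):
        m, labels = nb_matrix(
            rng, np.exp(rng.uniform(np.log(20), np.log(500), 300)), 20, 20
        )
        disp = estimate_dispersions(m, np.ones(40), labels)
        assert 0.05 <= np.median(disp) <= 0.2

    def test_constant_gene_floored(self):
        counts = np.full((1, 8), 7)
        m = matrix_from(counts)
        disp = estimate_dispersions(m, np.ones(8), ["a"] * 4 + ["b"] * 4)
        assert disp[0] <= 1e-6

    def test_small_group_raises(self):
        m = matrix_from(np.ones((3, 3), dtype=int))
        with pytest.raises(DesignError):
            estimate_dispersions(m, np.ones(3), ["a", "a", "b"])


class TestWaldTest:
    def test_type_one_error_calibrated(self, rng):
        """Null genes rejected at ~alpha under the estimated-dispersion Wald test."""
        mu = np.exp(rng.uniform(np.log(5), np.log(500), 1000))
        m, labels = nb_matrix(rng, mu, 14, 15)
        factors = size_factors(m)
        disp = estimate_dispersions(m, factors, labels)
        res = nb_wald_test(m, factors, disp, labels)
        p = res["p_value"].dropna()
        rate = (p < 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / len(p))
        assert abs(rate - 0.05) < band

    def test_lfc_recovery(self, rng):
        """High-expression genes with true log2 FC = 2 recovered within +-0.5."""
        mu = np.full(200, 200.0)
        m, labels = nb_matrix(rng, mu, 14, 15, lfc_ln=2 * np.log(2))
        factors = np.ones(29)  # net shift is real signal, not library size
        disp = estimate_dispersions(m, factors, labels)
        res = nb_wald_test(m, factors, disp, labels)
        assert abs(np.median(res["log2_fold_change"]) - 2.0) < 0.5

    def test_all_zero_gene_untested(self):
        counts = np.vstack([np.zeros(8, dtype=int), np.full(8, 50)])
        m = matrix_from(counts)
        res = nb_wald_test(m, np.ones(8), np.full(2, 0.1), ["a"] * 4 + ["b"] * 4)
        assert res.loc[0, "status"] == "untested"
        assert np.isnan(res.loc[0, "p_value"])
        assert res.loc[1, "status"] == "ok"

    def test_label_swap_negates_lfc(self, rng):
        mu = np.exp(rng.uniform(np.log(20), np.log(200), 50))
        m, labels = nb_matrix(rng, mu, 5, 6, lfc_ln=0.7)
        factors = size_factors(m)
        disp = estimate_dispersions(m, factors, labels)
        res_ab = nb_wald_test(m, factors, disp, labels)
        swapped = ["b" if l == "a" else "a" for l in labels]
        res_ba = nb_wald_test(m, factors, disp, swapped)
        ok = (res_ab["status"] == "ok") & (res_ba["status"] == "ok")
        np.testing.assert_allclose(
            res_ab.loc[ok, "log2_fold_change"],
            -res_ba.loc[ok, "log2_fold_change"],
            rtol=1e-6,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            res_ab.loc[ok, "p_value"], res_ba.loc[ok, "p_value"], rtol=1e-6
        )

    def test_normalization_consistency(self, rng):
        """Scaling a sample's counts by c together with its size factor.

        Normalised counts are unchanged, so the dispersion estimator is
        exactly invariant.  The GLM fold-change estimate is invariant in the
        dispersion-dominated limit (IRLS weights mu/(1+alpha*mu) equalise
        across samples); at moderate dispersion the estimate moves only
        slightly, because the GLM legitimately gives a deeper sample more
        weight.
        """
        mu = np.exp(rng.uniform(np.log(50), np.log(200), 40))
        m, labels = nb_matrix(rng, mu, 4, 4, alpha=0.1)
        factors = np.ones(8)
        scaled_counts = m.counts.copy()
        scaled_counts[:, 0] *= 3
        scaled = matrix_from(scaled_counts)
        scaled_factors = factors.copy()
        scaled_factors[0] *= 3.0

        disp1 = estimate_dispersions(m, factors, labels)
        disp2 = estimate_dispersions(scaled, scaled_factors, labels)
        np.testing.assert_allclose(disp1, disp2, rtol=1e-12)

        big = np.full(40, 50.0)  # alpha*mu >> 1: weights ~ constant
        res1 = nb_wald_test(m, factors, big, labels)
        res2 = nb_wald_test(scaled, scaled_factors, big, labels)
        np.testing.assert_allclose(
            res1["log2_fold_change"], res2["log2_fold_change"], rtol=0, atol=5e-3
        )

    def test_matches_statsmodels_glm(self, rng):
        """Coefficient and SE agree with an independent NB GLM fit per gene."""
        import statsmodels.api as sm

        mu = np.array([50.0, 120.0, 300.0, 30.0, 80.0])
        m, labels = nb_matrix(rng, mu, 6, 6, lfc_ln=0.5)
        factors = size_factors(m)
        disp = np.full(5, 0.1)
        res = nb_wald_test(m, factors, disp, labels)
        design = np.column_stack(
            [np.ones(12), np.array([0] * 6 + [1] * 6, dtype=float)]
        )
        for i in range(5):
            glm = sm.GLM(
                m.counts[i].astype(float),
                design,
                family=sm.families.NegativeBinomial(alpha=0.1),
                offset=np.log(factors),
            ).fit()
            assert res.loc[i, "log2_fold_change"] * np.log(2) == pytest.approx(
                glm.params[1], rel=1e-4, abs=1e-6
            )
            assert res.loc[i, "se"] * np.log(2) == pytest.approx(
                glm.bse[1], rel=1e-3
            )


class TestAdjustAndCall:
    def test_bh_hand_computation(self):
        res = _results_frame([0.01, 0.02, 0.03, 0.04], [1.0, -1.0, 1.0, 1.0])
        out = adjust_and_call(res, alpha=0.05)
        assert out["adjusted_p"].tolist() == pytest.approx([0.04] * 4)
        assert set(out["direction"]) == {"up", "down"}
        assert (out["direction"] != "ns").all()

    def test_all_null(self):
        out = adjust_and_call(_results_frame([1.0, 1.0], [0.5, -0.5]))
        assert (out["direction"] == "ns").all()

    def test_single_p_identity(self):
        out = adjust_and_call(_results_frame([0.04], [2.0]))
        assert out.loc[0, "adjusted_p"] == pytest.approx(0.04)
        assert out.loc[0, "direction"] == "up"

    def test_missing_p_excluded_from_family(self):
        res = _results_frame([0.025, np.nan], [1.0, 1.0])
        out = adjust_and_call(res)
        # m = 1: the missing gene must not inflate the BH family size
        assert out.loc[0, "adjusted_p"] == pytest.approx(0.025)
        assert out.loc[1, "direction"] == "ns"


def _results_frame(p_values, lfcs):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(p_values))],
            "log2_fold_change": lfcs,
            "p_value": p_values,
            "status": ["ok" if not np.isnan(p) else "failed" for p in p_values],
        }
    )


def test_run_de_recovers_signal(rng):
    """End-to-end DE on a synthetic truth: most calls are true positives."""
    mu = np.exp(rng.uniform(np.log(20), np.log(500), 400))
    size = 10.0
    n1 = n2 = 10
    lfc = np.zeros(400)
    lfc[:40] = 1.5  # strong effects in the first 40 genes
    m1 = np.repeat(mu[:, None], n1, axis=1)
    m2 = np.repeat((mu * np.exp(lfc))[:, None], n2, axis=1)
    counts = rng.negative_binomial(size, size / (size + np.concatenate([m1, m2], 1)))
    m = matrix_from(counts)
    out = run_de(m, ["a"] * n1 + ["b"] * n2)
    called = set(out.loc[out["direction"] != "ns", "gene_id"])
    truth = {f"g{i}" for i in range(40)}
    assert len(called & truth) >= 30
    fdp = len(called - truth) / max(len(called), 1)
    assert fdp <= 0.2
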