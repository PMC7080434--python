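import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from debra import BarcodeCountMatrix, bh_adjust, fit_nb_glm, run_debra
from debra.nb_testing import test_barcodes as compute_test
from debra.counts_io import SizeFactors, estimate_size_factors
from debra.dispersion import estimate_dispersions
from debra.nb_testing import _exact_nb_pvalue, fit_nb_glm as _fit

from .conftest import nb_count_matrix


def _two_group(K, n_c, n_t):
    K = np.asarray(K)
    return BarcodeCountMatrix(
        [f"b{i}" for i in range(K.shape[0])], K,
        [f"s{j}" for j in range(n_c + n_t)],
        ["control"] * n_c + ["test"] * n_t,
    )


def _fixed_dispersions(counts, alpha):
    """A DispersionSet carrying externally known dispersions."""
    from debra.dispersion import DispersionSet

    n = counts.n_barcodes
    alpha = np.broadcast_to(np.asarray(alpha, float), (n,)).copy()
    return DispersionSet(
        genewise=alpha, trend=lambda mu: alpha.mean() * np.ones_like(mu),
        final=alpha, method="trended", cap_value=float(alpha.max()),
        capped_mask=np.zeros(n, bool), allzero_mask=np.zeros(n, bool),
        means_test=np.zeros(n),
    )


class TestGLMFit:
    def test_log_fold_change_is_log_ratio_of_group_means(self):
        K = np.array([[50, 50, 100, 100]])
        m = _two_group(K, 2, 2)
        fit = fit_nb_glm(m, SizeFactors(np.ones(4)), _fixed_dispersions(m, 0.1))
        assert fit.condition[0] / np.log(2) == pytest.approx(1.0, abs=1e-6)

    def test_equal_group_means_give_zero_coefficient(self):
        K = np.array([[80, 80, 80, 80]])
        m = _two_group(K, 2, 2)
        fit = fit_nb_glm(m, SizeFactors(np.ones(4)), _fixed_dispersions(m, 0.1))
        assert abs(fit.condition[0]) < 1e-8

    def test_size_factor_offsets(self):
        # doubling a sample's counts and size factor leaves the fit unchanged
        K = np.array([[30, 60, 45, 90]])
        m = _two_group(K, 2, 2)
        fit = fit_nb_glm(
            m, SizeFactors([1.0, 2.0, 1.0, 2.0]), _fixed_dispersions(m, 0.2)
        )
        assert fit.condition[0] / np.log(2) == pytest.approx(
            np.log2(45 / 30), abs=1e-6
        )

    def test_all_zero_barcode_flagged(self):
        K = np.array([[0, 0, 0, 0], [5, 5, 5, 5]])
        m = _two_group(K, 2, 2)
        ds = _fixed_dispersions(m, 0.1)
        fit = fit_nb_glm(m, SizeFactors(np.ones(4)), ds)
        assert fit.zero_group[0]
        _, p = compute_test(m, SizeFactors(np.ones(4)), ds, method="wald", fit=fit)
        assert np.isnan(p[0])


class TestWaldAndLRT:
    def test_equal_means_large_counts(self):
        rng = np.random.default_rng(0)
        K = rng.poisson(10_000, size=(1, 8))
        m = _two_group(K, 4, 4)
        ds = _fixed_dispersions(m, 1e-4)
        fit = fit_nb_glm(m, SizeFactors(np.ones(8)), ds)
        z, p = compute_test(m, SizeFactors(np.ones(8)), ds, method="wald", fit=fit)
        assert abs(z[0]) < 2.0
        K = np.array([[10_000] * 8])
        m = _two_group(K, 4, 4)
        fit = fit_nb_glm(m, SizeFactors(np.ones(8)), ds)
        z, p = compute_test(m, SizeFactors(np.ones(8)), ds, method="wald", fit=fit)
        assert abs(z[0]) < 0.1 and p[0] > 0.9

    def test_wald_lrt_asymptotic_agreement(self):
        rng = np.random.default_rng(42)
        n = 2000
        mu = np.exp(rng.uniform(np.log(100), np.log(5000), n))
        alpha = np.full(n, 0.1)
        r = 1 / alpha
        K = rng.negative_binomial(r[:, None], (r / (r + mu))[:, None], (n, 4))
        m = _two_group(K, 2, 2)
        sf = SizeFactors(np.ones(4))
        ds = _fixed_dispersions(m, alpha)
        _, pw = compute_test(m, sf, ds, method="wald")
        _, pl = compute_test(m, sf, ds, method="lrt")
        assert np.nanmedian(np.abs(pw - pl)) < 0.02

    def test_zero_test_group_uses_lrt_fallback(self):
        K = np.array([[40, 45, 0, 0]])
        m = _two_group(K, 2, 2)
        sf = SizeFactors(np.ones(4))
        ds = _fixed_dispersions(m, 0.05)
        _, p = compute_test(m, sf, ds, method="wald")
        assert np.isfinite(p[0]) and 0 <= p[0] <= 1


class TestExactTest:
    @staticmethod
    def _enumeration_oracle(kc, kt, n_c, n_t, alpha_c, alpha_t):
        """Direct conditional enumeration with plain pmf arithmetic."""
        T = kc + kt
        mu = T / (n_c + n_t)
        r_c, r_t = n_c / alpha_c, n_t / alpha_t
        pc = r_c / (r_c + n_c * mu)
        pt = r_t / (r_t + n_t * mu)
        probs = [
            stats.nbinom.pmf(a, r_c, pc) * stats.nbinom.pmf(T - a, r_t, pt)
            for a in range(T + 1)
        ]
        obs = probs[kc]
        num = sum(q for q in probs if q <= obs * (1 + 1e-12))
        return num / sum(probs)

    @pytest.mark.parametrize(
        "kc,kt,alpha_c,alpha_t",
        [(10, 10, 0.01, 0.01), (3, 17, 0.05, 0.5), (0, 25, 0.2, 0.2),
         (40, 8, 0.01, 1.0)],
    )
    def test_matches_enumeration(self, kc, kt, alpha_c, alpha_t):
        p = _exact_nb_pvalue(kc, kt, 2, 2, alpha_c, alpha_t)
        oracle = self._enumeration_oracle(kc, kt, 2, 2, alpha_c, alpha_t)
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_balanced_split_is_not_significant(self):
        assert _exact_nb_pvalue(50, 50, 2, 2, 0.1, 0.1) > 0.5

    def test_exact_pipeline_runs(self):
        m = nb_count_matrix(n=300, reps=2, seed=1, mu_range=(5, 500),
                            group="control")
        K = np.hstack([m.counts, m.counts[:, ::-1]])
        cm = _two_group(K, 2, 2)
        sf = estimate_size_factors(cm)
        ds = _fixed_dispersions(cm, 0.2)
        stat, p = compute_test(cm, sf, ds, method="exact")
        ok = np.isfinite(p)
        assert ((p[ok] >= 0) & (p[ok] <= 1)).all()


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01], [0.01]),
            ([0.03, 0.04, 0.5, 0.6], [0.08, 0.08, 0.6, 0.6]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(bh_adjust(np.array(p)), expected, rtol=1e-12)

    def test_nan_passthrough(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1])
        assert np.isfinite(out[[0, 2]]).all()

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestRunDebra:
    def test_deterministic_given_seed(self, null_design):
        counts, _ = null_design
        r1, b1 = run_debra(counts, seed=5)
        r2, b2 = run_debra(counts, seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        assert b1.beta == b2.beta

    def test_beta_off_and_no_filter_matches_plain_test(self, null_design):
        counts, _ = null_design
        res, _ = run_debra(counts, beta_mode="off", apply_filter=False, seed=5)
        sf = estimate_size_factors(counts)
        ds = estimate_dispersions(counts, sf, method="trended", beta=None)
        fit = _fit(counts, sf, ds)
        _, p = compute_test(counts, sf, ds, method="wald", fit=fit)
        np.testing.assert_allclose(
            res["pvalue"].to_numpy(), p, rtol=1e-10, equal_nan=True
        )
        assert not res["filtered"].any()

    def test_null_false_call_fraction_bounded(self, null_design):
        counts, _ = null_design
        res, _ = run_debra(counts, dispersion_method="trended", seed=5)
        padj = np.nan_to_num(res["padj"].to_numpy(), nan=1.0)
        assert (padj < 0.25).mean() <= 0.25

    def test_type_i_error_on_equal_size_nb_null(self):
        fracs_w, fracs_l = [], []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            n = 5000
            mu = np.exp(rng.uniform(np.log(50), np.log(5000), n))
            alpha = 0.05 + 2 / mu
            r = 1 / alpha
            K = rng.negative_binomial(
                r[:, None], (r / (r + mu))[:, None], (n, 4)
            )
            m = _two_group(K, 2, 2)
            rw, _ = run_debra(m, method="wald", beta_mode="off",
                              apply_filter=False, seed=seed)
            rl, _ = run_debra(m, method="lrt", beta_mode="off",
                              apply_filter=False, seed=seed)
            fracs_w.append(np.nanmean(rw["pvalue"].to_numpy() < 0.05))
            fracs_l.append(np.nanmean(rl["pvalue"].to_numpy() < 0.05))
        for f in fracs_w + fracs_l:
            assert 0.03 <= f <= 0.07


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=60))
@settings(derandomize=True, max_examples=50)
def test_bh_bounds_and_order_preservation(pvals):
    p = np.asarray(pvals)
    padj = bh_adjust(p)
    assert ((padj >= p - 1e-12) & (padj <= 1 + 1e-12)).all()
    # BH preserves the p-value ordering of the adjusted values
    order = np.argsort(p, kind="stable")
    assert (np.diff(padj[order]) >= -1e-12).all()
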