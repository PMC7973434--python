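"""Moderated mixed-model machinery: trend, weights, correlation, GLS,
empirical-Bayes moderation, contrasts and BH — each against an independent
oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy import special

from sgafit.differential_fitness import (
    GeneFit,
    MeanVarTrend,
    adjust_bh,
    build_design,
    compute_weights,
    estimate_block_correlation,
    fit_gene_model,
    fit_trend,
    moderate_variances,
    run_differential,
)
from sgafit.differential_fitness import test_contrasts as moderated_contrasts
from sgafit.errors import ProcessingError

from conftest import cs_matrix


def bh_oracle(p):
    """Brute-force BH step-up: sort, scale by m/i, cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestAdjustBH:
    def test_single_p(self):
        assert adjust_bh(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_worked_step_up(self):
        padj = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])

    def test_oracle_equivalence_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            assert np.allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)

    def test_monotone_and_above_input(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        padj = adjust_bh(p)
        assert (padj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))


class TestGeneModel:
    def _random_instance(self, rng, n_blocks=8, k=3, p=3):
        blocks = np.repeat(np.arange(n_blocks), k)
        X = np.column_stack([np.ones(n_blocks * k), rng.standard_normal((n_blocks * k, p - 1))])
        y = rng.standard_normal(n_blocks * k)
        return y, X, blocks

    def test_gls_equals_ols_at_rho_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            y, X, blocks = self._random_instance(rng)
            w = np.ones(len(y))
            fit = fit_gene_model("g", y, X, w, 0.0, blocks, ["c%d" % i for i in range(X.shape[1])])
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            assert np.allclose(fit.beta, beta_ols, atol=1e-8)
            resid = y - X @ beta_ols
            s2_ols = resid @ resid / (len(y) - X.shape[1])
            assert fit.s2 == pytest.approx(s2_ols, abs=1e-8)

    def test_noiseless_data_exact_coefficients(self):
        X = np.column_stack([np.ones(12), np.repeat([0, 1], 6)])
        beta_true = np.array([0.5, -1.25])
        y = X @ beta_true
        blocks = np.repeat(np.arange(3), 4)
        fit = fit_gene_model("g", y, X, np.ones(12), 0.4, blocks, ["a", "b"])
        assert np.allclose(fit.beta, beta_true, atol=1e-12)

    def test_higher_rho_inflates_contrast_se(self):
        # block-constant design (as for query/batch terms): correlated
        # replicates mean fewer effective observations per block, so the
        # contrast variance must grow with rho
        rng = np.random.default_rng(3)
        n_blocks, k = 6, 4
        blocks = np.repeat(np.arange(n_blocks), k)
        group = np.repeat(np.arange(n_blocks) % 2, k).astype(float)
        X = np.column_stack([np.ones(n_blocks * k), group])
        y = rng.standard_normal(n_blocks * k)
        c = np.array([0.0, 1.0])
        ses = []
        for rho in (0.0, 0.9):
            fit = fit_gene_model("g", y, X, np.ones(len(y)), rho, blocks, ["a", "b"])
            ses.append(c @ fit.cov_unscaled @ c)
        assert ses[1] > ses[0]

    def test_rank_deficient_returns_none(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        fit = fit_gene_model("g", np.zeros(8), X, np.ones(8), 0.0,
                             np.repeat([0, 1], 4), ["a", "b"])
        assert fit is None


class TestModeration:
    def test_equal_variances_give_infinite_prior_df(self):
        mod = moderate_variances(np.full(50, 2.0), np.full(50, 6.0))
        assert np.isinf(mod.d0)
        assert np.allclose(mod.s_tilde_sq, 2.0, rtol=1e-6)

    def test_pooling_formula(self):
        # posterior = (d0*s0^2 + d*s^2)/(d0+d): (4*2 + 6*5)/10 = 3.8
        d0, s0_sq, d, s2 = 4.0, 2.0, 6.0, 5.0
        assert (d0 * s0_sq + d * s2) / (d0 + d) == pytest.approx(3.8)
        rng = np.random.default_rng(4)
        s2_all = s0_sq * d0 / st.chi2.rvs(d0, size=3000, random_state=rng)
        mod = moderate_variances(s2_all, np.full(3000, d))
        i = 42
        expect = (mod.d0 * mod.s0_sq + d * s2_all[i]) / (mod.d0 + d)
        assert mod.s_tilde_sq[i] == pytest.approx(expect)

    def test_prior_df_recovery_scaled_inv_chisq(self):
        d0_true, s0_true, d = 10.0, 1.5, 8
        rng = np.random.default_rng(5)
        # s2 ~ s0^2 * (chi2_d/d) scaled-inverse prior: sample gene variances
        # then residual variances around them
        sigma2 = s0_true * d0_true / st.chi2.rvs(d0_true, size=2000, random_state=rng)
        s2 = sigma2 * st.chi2.rvs(d, size=2000, random_state=rng) / d
        mod = moderate_variances(s2, np.full(2000, float(d)))
        assert mod.d0 == pytest.approx(d0_true, rel=0.3)

    def test_shrinkage_toward_prior_and_monotone(self):
        rng = np.random.default_rng(6)
        s2 = st.chi2.rvs(6, size=500, random_state=rng) / 6 * np.exp(rng.normal(0, 0.7, 500))
        d = np.full(500, 6.0)
        mod = moderate_variances(s2, d)
        assert np.isfinite(mod.d0)
        lo = np.minimum(s2, mod.s0_sq) - 1e-12
        hi = np.maximum(s2, mod.s0_sq) + 1e-12
        assert ((mod.s_tilde_sq >= lo) & (mod.s_tilde_sq <= hi)).all()
        order = np.argsort(s2)
        assert (np.diff(mod.s_tilde_sq[order]) > -1e-12).all()

    def test_all_zero_variances_error(self):
        with pytest.raises(ProcessingError):
            moderate_variances(np.zeros(20), np.full(20, 5.0))


class TestTrendAndWeights:
    def test_flat_trend_on_homoscedastic_data(self):
        m = cs_matrix(300, 0.0, seed=7, sd=0.4)
        trend = fit_trend(m, "ctrl")
        pred = trend.predict_sqrt_sd(np.array([-0.3, 0.0, 0.3]))
        assert np.allclose(pred, np.sqrt(0.4), rtol=0.1)

    def test_sd_inflation_at_small_means_detected(self):
        rng = np.random.default_rng(8)
        frames = []
        # half the genes shifted down by 2 log2 units with doubled SD
        for shift, sd, tag in ((0.0, 0.3, "hi"), (-2.0, 0.6, "lo")):
            sub = cs_matrix(200, 0.0, seed=int(rng.integers(1e6)), sd=sd)
            sub["value"] += shift
            sub["gene_id"] = tag + sub["gene_id"]
            frames.append(sub)
        m = pd.concat(frames, ignore_index=True)
        trend = fit_trend(m, "ctrl")
        assert trend.predict_sd(np.array([-2.0]))[0] >= 1.5 * trend.predict_sd(np.array([0.0]))[0]

    def test_single_knot_constant_everywhere(self):
        trend = MeanVarTrend(np.array([0.0]), np.array([0.7]))
        assert np.allclose(trend.predict_sqrt_sd(np.array([-5, 0, 5])), 0.7)

    def test_weights_are_inverse_predicted_variance(self):
        trend = MeanVarTrend(np.array([0.0, 1.0]), np.array([0.5, 1.0]))
        w = compute_weights(trend, np.array([0.0, 1.0, 0.5]))
        assert w[0] == pytest.approx(0.5**-4)
        assert w[1] == pytest.approx(1.0**-4)
        # halving predicted sqrt-SD multiplies the weight by 16
        assert w[0] / w[1] == pytest.approx(16.0)


class TestBlockCorrelation:
    def test_perfect_within_block_agreement(self):
        rng = np.random.default_rng(9)
        m = cs_matrix(60, 0.0, seed=1)
        # overwrite: all 4 values of each block identical, blocks vary
        blocks = m.groupby("block_id").ngroup()
        m["value"] = rng.standard_normal(blocks.max() + 1)[blocks]
        cc = estimate_block_correlation(m, "ctrl")
        assert cc.consensus >= 0.95

    def test_independent_data_near_zero(self):
        cc = estimate_block_correlation(cs_matrix(500, 0.0, seed=10), "ctrl")
        assert abs(cc.consensus) <= 0.05

    def test_recovers_rho_half(self):
        cc = estimate_block_correlation(cs_matrix(500, 0.5, seed=11), "ctrl")
        assert cc.consensus == pytest.approx(0.5, abs=0.1)

    def test_singleton_blocks_error(self):
        m = cs_matrix(20, 0.0, seed=12, k=1)
        with pytest.raises(ProcessingError):
            estimate_block_correlation(m, "ctrl")


class TestContrasts:
    def _fits(self, betas, s2=1.0, df=6):
        cov = np.eye(2) * 0.1
        return [
            GeneFit(f"g{i}", np.array(b, dtype=float), cov, s2, df, ["a", "b"])
            for i, b in enumerate(betas)
        ]

    def test_zero_effect_gives_t_zero_p_one(self):
        fits = self._fits([[0.3, 0.0]])
        mod = moderate_variances(np.full(12, 1.0), np.full(12, 6.0))
        mod.s_tilde_sq = mod.s_tilde_sq[:1]
        table = moderated_contrasts(fits, mod, {"c": np.array([0.0, 1.0])})
        assert table["t"].iloc[0] == 0.0
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_infinite_prior_df_matches_pooled_z(self):
        fits = self._fits([[0.0, 0.5]])
        mod = moderate_variances(np.full(30, 2.0), np.full(30, 6.0))  # d0 = inf
        mod.s_tilde_sq = mod.s_tilde_sq[:1]
        table = moderated_contrasts(fits, mod, {"c": np.array([0.0, 1.0])})
        z = 0.5 / np.sqrt(2.0 * 0.1)
        assert table["t"].iloc[0] == pytest.approx(z)
        assert table["p"].iloc[0] == pytest.approx(2 * st.norm.sf(z), rel=1e-9)

    def test_null_pvalues_uniform(self):
        m = cs_matrix(2000, 0.25, seed=13)
        fits = run_differential(m, control="ctrl")
        pv = fits.loc[fits["contrast"] == "mutA-ctrl", "p"].values
        assert st.kstest(pv, "uniform").pvalue > 0.01


class TestRunDifferential:
    def test_sign_agreement_with_planted_effects(self):
        rng = np.random.default_rng(14)
        effects = {}
        for i in rng.choice(400, size=40, replace=False):
            effects[(f"g{i:04d}", "mutA")] = float(rng.choice([-1.0, 1.0]))
        m = cs_matrix(400, 0.25, seed=15, sd=0.3, effects=effects)
        fits = run_differential(m, control="ctrl")
        called = fits[(fits["contrast"] == "mutA-ctrl") & (fits["padj"] < 0.05)]
        truth_sign = {g: np.sign(d) for (g, _), d in effects.items()}
        match = [
            np.sign(e) == truth_sign.get(g, np.sign(e))
            for g, e in zip(called["gene_id"], called["effect"])
        ]
        assert len(called) >= 30
        assert np.mean(match) >= 0.95

    def test_deterministic_rerun(self, small_screen):
        a = run_differential(small_screen["matrix"], control="ctrl", reference="mutA")
        b = run_differential(small_screen["matrix"], control="ctrl", reference="mutA")
        pd.testing.assert_frame_equal(a, b)

    def test_contrast_set(self, small_fits):
        contrasts = set(small_fits["contrast"])
        assert contrasts == {
            "mutA-ctrl", "mutB-ctrl", "mutC-ctrl", "mutB-mutA", "mutC-mutA",
        }

    def test_padj_properties(self, small_fits):
        for _, sub in small_fits.groupby("contrast"):
            assert (sub["padj"] >= sub["p"] - 1e-15).all()
            order = np.argsort(sub["p"].values)
            assert (np.diff(sub["padj"].values[order]) >= -1e-15).all()


def test_trigamma_inverse_roundtrip():
    from sgafit.differential_fitness import _trigamma_inverse

    for y in (0.01, 0.1, 0.5, 2.0, 20.0):
        x = _trigamma_inverse(y)
        assert special.polygamma(1, x) == pytest.approx(y, rel=1e-6)
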