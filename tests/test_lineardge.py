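import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synergyseq import lineardge, normfilter
from synergyseq.lineardge import (
    ContrastResult,
    adjust_fdr,
    build_design,
    estimate_prior,
    fit_contrasts,
    mean_variance_weights,
    moderate_statistics,
)
from synergyseq.simdata import SimulationConfig, simulate_counts


def _wls_oracle(y, w, x, c):
    """Independent generic weighted-regression computation for one gene."""
    W = np.diag(w)
    xtwx_inv = np.linalg.inv(x.T @ W @ x)
    beta = xtwx_inv @ x.T @ W @ y
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    s2 = float(resid @ W @ resid) / df
    return float(c @ beta), float(np.sqrt(c @ xtwx_inv @ c)), s2


class TestDesign:
    def test_study_design_shape_and_column_sums(self, study_samples):
        design, contrasts = build_design(study_samples)
        assert design.shape == (14, 4)
        assert design.sum(axis=0).tolist() == [4, 3, 4, 3]
        assert (design.sum(axis=1) == 1).all()
        assert {"SZ_vs_CTRL", "JQ_vs_CTRL", "SZJQ_vs_CTRL", "SYNERGY"} <= set(
            contrasts
        )

    def test_synergy_contrast_identities(self, study_samples):
        _, contrasts = build_design(study_samples)
        syn = contrasts["SYNERGY"]
        assert syn.sum() == 0
        # +1 on each diagonal pair: (CTRL_VEH, SZ_JQ) and -(SZ_VEH, CTRL_JQ)
        assert syn[0] + syn[3] == 2
        assert syn[1] + syn[2] == -2

    def test_row_permutation_leaves_coefficients_unchanged(
        self, study_samples, rng
    ):
        y = pd.DataFrame(
            rng.normal(size=(20, 14)),
            columns=study_samples["sample_id"],
        )
        design, contrasts = build_design(study_samples)
        fit = fit_contrasts(y, None, design, contrasts)
        perm = rng.permutation(14)
        samples_p = study_samples.iloc[perm].reset_index(drop=True)
        design_p, _ = build_design(samples_p)
        fit_p = fit_contrasts(y[samples_p["sample_id"]], None, design_p, contrasts)
        pd.testing.assert_frame_equal(fit.coef, fit_p.coef)

    def test_unknown_level_rejected(self, study_samples):
        bad = study_samples.copy()
        bad.loc[0, "diagnosis"] = "BIPOLAR"
        with pytest.raises(ValueError):
            build_design(bad)


class TestWeights:
    def test_homoscedastic_data_gets_flat_weights(self, study_samples, rng):
        # mean-independent noise: trend is flat, weights within a 2x band
        y = pd.DataFrame(
            rng.normal(0, 1, size=(500, 14))
            + rng.uniform(2, 12, size=500)[:, None],
            columns=study_samples["sample_id"],
        )
        y.attrs["effective_lib_sizes"] = pd.Series(
            1e7, index=y.columns
        )
        design, _ = build_design(study_samples)
        w, _ = mean_variance_weights(y, design)
        ratio = w.to_numpy().max() / w.to_numpy().min()
        q = np.quantile(w.to_numpy(), [0.005, 0.995])
        assert q[1] / q[0] < 2.0

    def test_low_expression_genes_downweighted_under_nb_noise(self):
        cfg = SimulationConfig(n_genes=2000, effect_fractions=(0, 0, 0), seed=9)
        counts, samples, _ = simulate_counts(cfg)
        filtered = normfilter.filter_low_expression(counts)
        logexpr = normfilter.log_cpm(filtered, normfilter.tmm_factors(filtered))
        design, _ = build_design(samples)
        w, _ = mean_variance_weights(logexpr, design)
        mean_expr = logexpr.mean(axis=1)
        lo = w[mean_expr <= mean_expr.quantile(0.1)].to_numpy().mean()
        hi = w[mean_expr >= mean_expr.quantile(0.9)].to_numpy().mean()
        assert lo < hi

    def test_trend_is_clamped_outside_fitted_range(self, study_samples, rng):
        y = pd.DataFrame(
            rng.normal(size=(100, 14)) + np.linspace(0, 10, 100)[:, None],
            columns=study_samples["sample_id"],
        )
        design, _ = build_design(study_samples)
        w, trend = mean_variance_weights(y, design)
        assert np.isfinite(w.to_numpy()).all()
        assert (w.to_numpy() > 0).all()
        lo_w = np.interp(-1e6, trend["log2_count"], trend["sqrt_sd"]) ** -4
        assert lo_w == pytest.approx(trend["sqrt_sd"].iloc[0] ** -4)


class TestFit:
    def test_two_group_closed_form(self):
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "diagnosis": ["CTRL"] * 4 + ["SZ"] * 4,
                "treatment": ["VEH"] * 8,
            }
        )
        design, contrasts = build_design(samples)
        rng = np.random.default_rng(0)
        y = pd.DataFrame(
            rng.normal(size=(30, 8)), columns=samples["sample_id"]
        )
        fit = fit_contrasts(y, None, design, {"SZ_vs_CTRL": contrasts["SZ_vs_CTRL"]})
        expected = y.iloc[:, 4:].mean(axis=1) - y.iloc[:, :4].mean(axis=1)
        assert np.allclose(fit.coef["SZ_vs_CTRL"], expected, atol=1e-12)
        # residual variance equals the pooled within-group variance
        pooled = (y.iloc[:, :4].var(axis=1) * 3 + y.iloc[:, 4:].var(axis=1) * 3) / 6
        assert np.allclose(fit.sigma**2, pooled, atol=1e-12)

    def test_synergy_equals_contrast_combination(self, study_samples, rng):
        design, contrasts = build_design(study_samples)
        y = pd.DataFrame(
            rng.normal(size=(100, 14)), columns=study_samples["sample_id"]
        )
        w = pd.DataFrame(
            rng.uniform(0.2, 5, size=(100, 14)), columns=study_samples["sample_id"]
        )
        fit = fit_contrasts(y, w, design, contrasts)
        lhs = fit.coef["SYNERGY"]
        rhs = (
            fit.coef["SZJQ_vs_CTRL"]
            - fit.coef["SZ_vs_CTRL"]
            - fit.coef["JQ_vs_CTRL"]
        )
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_matches_generic_wls_oracle(self, study_samples, rng):
        design, contrasts = build_design(study_samples)
        x = design.to_numpy()
        y = pd.DataFrame(
            rng.normal(size=(50, 14)), columns=study_samples["sample_id"]
        )
        w = pd.DataFrame(
            rng.uniform(0.5, 3, size=(50, 14)), columns=study_samples["sample_id"]
        )
        fit = fit_contrasts(y, w, design, contrasts)
        c = contrasts["SYNERGY"]
        for g in range(50):
            beta, u, s2 = _wls_oracle(
                y.to_numpy()[g], w.to_numpy()[g], x, c
            )
            assert fit.coef["SYNERGY"].iloc[g] == pytest.approx(beta, abs=1e-10)
            assert fit.se_unscaled["SYNERGY"].iloc[g] == pytest.approx(u, abs=1e-10)
            assert fit.sigma.iloc[g] ** 2 == pytest.approx(s2, abs=1e-10)

    def test_weight_rescaling_leaves_t_unchanged(self, study_samples, rng):
        design, contrasts = build_design(study_samples)
        y = pd.DataFrame(
            rng.normal(size=(40, 14)), columns=study_samples["sample_id"]
        )
        w = pd.DataFrame(
            rng.uniform(0.5, 3, size=(40, 14)), columns=study_samples["sample_id"]
        )
        f1 = moderate_statistics(fit_contrasts(y, w, design, contrasts))
        f2 = moderate_statistics(fit_contrasts(y, w * 7.3, design, contrasts))
        assert np.allclose(f1.t.to_numpy(), f2.t.to_numpy(), atol=1e-8)


class TestModeration:
    def test_prior_matches_limma_squeezevar(self):
        """Frozen oracle: limma::squeezeVar on the regenerated variance
        sample gives df.prior 8.401434 and var.prior 0.2502979."""
        rng = np.random.default_rng(2024)
        d, d0, s0sq = 10, 8.0, 0.25
        s2 = s0sq * (rng.chisquare(d, 3000) / d) / (rng.chisquare(d0, 3000) / d0)
        est_d0, est_s0 = estimate_prior(s2, d)
        assert est_d0 == pytest.approx(8.401434, abs=1e-4)
        assert est_s0 == pytest.approx(0.2502979, abs=1e-6)
        # and it recovers the generating prior
        assert 6 <= est_d0 <= 16
        assert est_s0 == pytest.approx(s0sq, rel=0.2)

    def test_infinite_prior_shrinks_to_common_variance(self, study_samples, rng):
        design, contrasts = build_design(study_samples)
        y = pd.DataFrame(
            rng.normal(size=(30, 14)), columns=study_samples["sample_id"]
        )
        fit = fit_contrasts(y, None, design, contrasts)
        mod = moderate_statistics(fit, d0=np.inf, s0_sq=0.7)
        expected = fit.coef["SYNERGY"] / (
            fit.se_unscaled["SYNERGY"] * np.sqrt(0.7)
        )
        assert np.allclose(mod.t["SYNERGY"], expected, atol=1e-12)

    def test_zero_prior_reproduces_ordinary_t(self, study_samples, rng):
        design, contrasts = build_design(study_samples)
        y = pd.DataFrame(
            rng.normal(size=(30, 14)), columns=study_samples["sample_id"]
        )
        fit = fit_contrasts(y, None, design, contrasts)
        mod = moderate_statistics(fit, d0=0.0, s0_sq=1.0)
        ordinary = fit.coef["SYNERGY"] / (fit.se_unscaled["SYNERGY"] * fit.sigma)
        assert np.allclose(mod.t["SYNERGY"], ordinary, atol=1e-12)
        p = 2 * stats.t.sf(np.abs(ordinary), fit.df_residual)
        assert np.allclose(mod.p["SYNERGY"], p, atol=1e-12)

    def test_posterior_variance_is_convex_combination(self, small_sim):
        from synergyseq import workflow

        counts, samples, _ = small_sim
        fit, _, _ = workflow.run_differential_expression(counts, samples)
        s2 = fit.sigma**2
        lo = np.minimum(s2, fit.s0_sq)
        hi = np.maximum(s2, fit.s0_sq)
        assert ((fit.s2_post >= lo - 1e-12) & (fit.s2_post <= hi + 1e-12)).all()


class TestFdr:
    def test_hand_computed_bh_example(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_bh_controls_fdr_under_uniform_null(self, rng):
        frac = [
            (adjust_fdr(rng.uniform(size=2000)) <= 0.05).mean()
            for _ in range(30)
        ]
        assert np.mean(frac) <= 0.05

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all()
        assert (q <= 1).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.2])
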