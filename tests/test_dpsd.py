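"""Dual-process signal-detection model: ROC construction and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr
from scipy.stats import norm

from dualproc.cohort import DEFAULT_CRITERIA, dpsd_confidence_probs
from dualproc.dpsd import (
    ConfidenceCounts,
    DPSDModel,
    DPSDParams,
    dpsd_predict,
    fit_dpsd,
    roc_from_counts,
    zroc_slope,
)


def simulate_counts(R, dprime, n, seed, criteria=DEFAULT_CRITERIA):
    rng = np.random.default_rng(seed)
    p_t, p_f = dpsd_confidence_probs(R, dprime, criteria)
    return ConfidenceCounts(tuple(rng.multinomial(n, p_t)),
                            tuple(rng.multinomial(n, p_f)))


class TestROCFromCounts:
    @pytest.mark.parametrize("targets,foils,exp_h,exp_fa", [
        # perfect memory: all targets "definitely old", all foils "definitely new"
        ((0, 0, 0, 0, 0, 10), (10, 0, 0, 0, 0, 0),
         (1, 1, 1, 1, 1), (0, 0, 0, 0, 0)),
        # chance: uniform confidence for both item types
        ((10,) * 6, (10,) * 6,
         (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6), (1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6)),
        # hand-cumulated proportions
        ((5, 5, 10, 10, 20, 30), (30, 20, 10, 10, 5, 5),
         (0.375, 0.625, 0.75, 0.875, 0.9375), (0.0625, 0.125, 0.25, 0.375, 0.625)),
    ])
    def test_cumulation(self, targets, foils, exp_h, exp_fa):
        roc = roc_from_counts(ConfidenceCounts(targets, foils))
        np.testing.assert_allclose(roc.hit_rates, exp_h)
        np.testing.assert_allclose(roc.fa_rates, exp_fa)

    def test_zero_one_adjustment_replaces_boundary_rates(self):
        roc = roc_from_counts(ConfidenceCounts((0, 0, 0, 0, 0, 10),
                                               (10, 0, 0, 0, 0, 0)),
                              zero_one_adjust=True)
        assert roc.hit_rates[0] == pytest.approx(1 - 1 / 20)
        assert roc.fa_rates[0] == pytest.approx(1 / 20)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            roc_from_counts(ConfidenceCounts((0,) * 6, (1, 0, 0, 0, 0, 0)))

    @given(st.lists(st.integers(0, 50), min_size=6, max_size=6),
           st.lists(st.integers(0, 50), min_size=6, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_cumulative_rates_monotone(self, t, f):
        if sum(t) == 0 or sum(f) == 0:
            return
        roc = roc_from_counts(ConfidenceCounts(tuple(t), tuple(f)))
        assert np.all(np.diff(roc.hit_rates) >= -1e-12)
        assert np.all(np.diff(roc.fa_rates) >= -1e-12)


class TestPredict:
    def test_null_model_lies_on_diagonal(self):
        h, fa = dpsd_predict(DPSDParams(0.0, 0.0, DEFAULT_CRITERIA))
        np.testing.assert_allclose(h, fa)

    def test_certain_recollection_saturates_hits(self):
        h, _ = dpsd_predict(DPSDParams(1.0, 0.7, DEFAULT_CRITERIA))
        np.testing.assert_allclose(h, 1.0)

    def test_closed_form_at_zero_criterion(self):
        # H = R + (1-R) * Phi(d' - c) with c = 0 in the middle position
        h, fa = dpsd_predict(DPSDParams(0.3, 1.0, DEFAULT_CRITERIA))
        assert h[2] == pytest.approx(0.3 + 0.7 * norm.cdf(1.0), abs=1e-9)
        assert fa[2] == pytest.approx(0.5)

    def test_category_probabilities_sum_to_one(self):
        p_t, p_f = dpsd_confidence_probs(0.4, 1.3, DEFAULT_CRITERIA)
        assert p_t.sum() == pytest.approx(1.0)
        assert p_f.sum() == pytest.approx(1.0)


class TestZROCSlope:
    def test_equal_variance_limit_has_unit_slope(self):
        h, fa = dpsd_predict(DPSDParams(0.0, 1.0, DEFAULT_CRITERIA))
        from dualproc.dpsd import ROCCurve
        assert zroc_slope(ROCCurve(tuple(h), tuple(fa))) == pytest.approx(1.0)

    def test_recollection_flattens_zroc(self):
        h, fa = dpsd_predict(DPSDParams(0.4, 0.8, DEFAULT_CRITERIA))
        from dualproc.dpsd import ROCCurve
        assert zroc_slope(ROCCurve(tuple(h), tuple(fa))) < 1.0

    def test_boundary_rates_rejected(self):
        from dualproc.dpsd import ROCCurve
        curve = ROCCurve((0.2, 0.4, 0.6, 0.8, 1.0), (0.1, 0.2, 0.3, 0.4, 0.5))
        with pytest.raises(ValueError):
            zroc_slope(curve)


class TestFit:
    def test_null_recovery_from_uniform_counts(self):
        res = fit_dpsd(ConfidenceCounts((100,) * 6, (100,) * 6), seed=0,
                       smooth=False)
        assert res.R <= 0.01
        assert abs(res.dprime) <= 0.01

    def test_large_sample_recovery_matches_grid_oracle(self):
        """Optimizer solution agrees with brute-force (R, d') grid search.

        The oracle profiles each criterion out independently (a lower bound
        on the SSE, exact when ordering is inactive) on a dense grid.
        """
        counts = simulate_counts(0.3, 1.0, 10000, seed=2024)
        model = DPSDModel(counts)
        h_obs, fa_obs = model._h_obs, model._fa_obs
        c_grid = np.linspace(-4, 6, 2001)
        fa_err = (fa_obs[:, None] - ndtr(-c_grid)[None, :]) ** 2
        best = (np.inf, None, None)
        for R in np.arange(0, 0.61, 0.01):
            hp = R + (1 - R) * ndtr(np.arange(0.4, 1.61, 0.01)[:, None]
                                    - c_grid[None, :])
            for i_d, d in enumerate(np.arange(0.4, 1.61, 0.01)):
                err = (h_obs[:, None] - hp[i_d][None, :]) ** 2 + fa_err
                sse = err.min(axis=1).sum()
                if sse < best[0]:
                    best = (sse, R, d)
        res = model.fit(seed=3)
        assert res.R == pytest.approx(best[1], abs=0.0101)
        assert res.dprime == pytest.approx(best[2], abs=0.0101)
        # continuous criteria can only improve on the profiled grid optimum
        assert res.objective_value <= best[0] + 1e-9

    def test_fit_is_locally_optimal(self):
        """Perturbing any parameter by +-0.05 never beats the optimum."""
        counts = simulate_counts(0.35, 1.1, 200, seed=5)
        model = DPSDModel(counts)
        res = model.fit(seed=5)
        from dualproc.dpsd import _pack
        x_opt = _pack(res.R, res.dprime, res.params.criteria)
        for j in range(2):  # R and d'; criteria are checked via repacking below
            for delta in (-0.05, 0.05):
                x = x_opt.copy()
                x[j] = np.clip(x[j] + delta, 0 if j == 0 else -np.inf, 1 if j == 0 else np.inf)
                assert model._objective_value(x) >= res.objective_value - 1e-9
        for k in range(5):
            for delta in (-0.05, 0.05):
                c = np.asarray(res.params.criteria, float)
                c[k] += delta
                if np.any(np.diff(c) <= 0):
                    continue
                x = _pack(res.R, res.dprime, c)
                assert model._objective_value(x) >= res.objective_value - 1e-9

    def test_r_fixed_zero_matches_closed_form_sdt(self):
        """With no recollection in the data, fitted d' agrees with the
        closed-form z(H) - z(FA) of the collapsed middle criterion."""
        counts = simulate_counts(0.0, 1.2, 20000, seed=9)
        res = fit_dpsd(counts, seed=9, smooth=False)
        assert res.R <= 0.02
        roc = roc_from_counts(counts, zero_one_adjust=True)
        closed = norm.ppf(roc.hit_rates[2]) - norm.ppf(roc.fa_rates[2])
        assert res.dprime == pytest.approx(closed, abs=0.02)

    def test_sse_and_mle_rank_r_consistently(self):
        """The two objectives order participants' R the same way."""
        from scipy.stats import spearmanr
        truths = np.linspace(0.05, 0.7, 12)
        r_sse, r_mle = [], []
        for i, R in enumerate(truths):
            counts = simulate_counts(R, 1.2, 80, seed=100 + i)
            r_sse.append(fit_dpsd(counts, seed=i, restarts=5).R)
            r_mle.append(fit_dpsd(counts, objective="mle", seed=i, restarts=5).R)
        rho = spearmanr(r_sse, r_mle).statistic
        assert rho > 0.9

    def test_degenerate_counts_flagged_not_raised(self):
        res = fit_dpsd(ConfidenceCounts((0, 0, 0, 0, 0, 50),
                                        (0, 0, 0, 0, 0, 50)), smooth=False)
        assert not res.converged

    def test_summary_mentions_parameters(self):
        res = fit_dpsd(simulate_counts(0.3, 1.0, 500, seed=1), seed=1)
        text = res.summary()
        assert "recollection" in text and "familiarity" in text

    def test_roc_plot_renders(self):
        import matplotlib
        matplotlib.use("Agg")
        res = fit_dpsd(simulate_counts(0.3, 1.0, 200, seed=2), seed=2)
        ax = res.plot_roc()
        assert ax.get_xlabel() == "false-alarm rate"
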