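"""Dual-process signal-detection (DPSD) modelling of confidence-rating ROCs.

The DPSD model assumes recognition of a studied item (target) succeeds
either through *recollection* — an all-or-none threshold process that
occurs with probability ``R`` and yields a high-confidence "old" response —
or, failing that, through *familiarity*, an equal-variance Gaussian
signal-detection process with discriminability ``d'``.  With response
criteria ``c_1 < ... < c_5`` partitioning the strength axis into six
confidence categories, the cumulative hit and false-alarm rates at
criterion ``i`` are

    H_i  = R + (1 - R) * Phi(d' - c_i)
    FA_i = Phi(-c_i)

where ``Phi`` is the standard normal CDF.  Foils are never recollected.

Fitting minimises, by default, the sum of squared errors between observed
and predicted cumulative ROC points (the classic spreadsheet approach used
throughout the dual-process literature); a multinomial maximum-likelihood
objective over the six response categories is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import norm

from ._rng import substream

__all__ = [
    "ConfidenceCounts",
    "ROCCurve",
    "DPSDParams",
    "DPSDModel",
    "DPSDResults",
    "roc_from_counts",
    "dpsd_predict",
    "dpsd_category_probs",
    "fit_dpsd",
    "zroc_slope",
]

N_CATEGORIES = 6
N_CRITERIA = 5


@dataclass(frozen=True)
class ConfidenceCounts:
    """Per-condition response counts on the 6-point confidence scale.

    Category 1 = "definitely new" ... category 6 = "definitely old".
    """

    target_counts: tuple
    foil_counts: tuple

    def __post_init__(self):
        t = np.asarray(self.target_counts)
        f = np.asarray(self.foil_counts)
        for name, v in (("target_counts", t), ("foil_counts", f)):
            if v.shape != (N_CATEGORIES,):
                raise ValueError(f"{name} must have {N_CATEGORIES} entries")
            if np.any(v < 0) or not np.allclose(v, np.round(v)):
                raise ValueError(f"{name} must be nonnegative integers")
        object.__setattr__(self, "target_counts", tuple(int(x) for x in t))
        object.__setattr__(self, "foil_counts", tuple(int(x) for x in f))

    @property
    def n_targets(self) -> int:
        return int(sum(self.target_counts))

    @property
    def n_foils(self) -> int:
        return int(sum(self.foil_counts))

    @classmethod
    def from_trials(cls, confidence, item_status) -> "ConfidenceCounts":
        """Tally counts from trial-level vectors.

        Parameters
        ----------
        confidence : sequence of int in 1..6
        item_status : sequence of {"target", "foil"}
        """
        conf = np.asarray(confidence, dtype=int)
        status = np.asarray(item_status)
        if conf.min() < 1 or conf.max() > N_CATEGORIES:
            raise ValueError("confidence ratings must lie in 1..6")
        tc = np.bincount(conf[status == "target"], minlength=7)[1:7]
        fc = np.bincount(conf[status == "foil"], minlength=7)[1:7]
        return cls(tuple(tc), tuple(fc))


@dataclass(frozen=True)
class ROCCurve:
    """Cumulative (FA_i, H_i) points, most conservative criterion first."""

    hit_rates: tuple
    fa_rates: tuple

    def __post_init__(self):
        h = np.asarray(self.hit_rates, float)
        f = np.asarray(self.fa_rates, float)
        if h.shape != (N_CRITERIA,) or f.shape != (N_CRITERIA,):
            raise ValueError(f"ROC requires {N_CRITERIA} cumulative points")
        if np.any((h < 0) | (h > 1) | (f < 0) | (f > 1)):
            raise ValueError("rates must lie in [0, 1]")
        if np.any(np.diff(h) < -1e-12) or np.any(np.diff(f) < -1e-12):
            raise ValueError("cumulative rates must be non-decreasing")
        object.__setattr__(self, "hit_rates", tuple(float(x) for x in h))
        object.__setattr__(self, "fa_rates", tuple(float(x) for x in f))


@dataclass(frozen=True)
class DPSDParams:
    """Recollection probability, familiarity d', and ordered criteria."""

    R: float
    dprime: float
    criteria: tuple

    def __post_init__(self):
        if not 0.0 <= self.R <= 1.0:
            raise ValueError("R must lie in [0, 1]")
        c = np.asarray(self.criteria, float)
        if c.shape != (N_CRITERIA,):
            raise ValueError(f"expected {N_CRITERIA} criteria")
        if not np.all(np.isfinite(c)) or np.any(np.diff(c) <= 0):
            raise ValueError("criteria must be finite and strictly increasing")
        if not np.isfinite(self.dprime):
            raise ValueError("dprime must be finite")
        object.__setattr__(self, "criteria", tuple(float(x) for x in c))


def roc_from_counts(counts: ConfidenceCounts, zero_one_adjust: bool = False) -> ROCCurve:
    """Cumulate confidence counts into ROC points.

    ``H_i`` is the proportion of targets rated at or above confidence
    ``7 - i`` (i.e. cumulating from "definitely old" downward), and
    likewise ``FA_i`` for foils.  With ``zero_one_adjust``, proportions of
    exactly 0 or 1 are replaced by ``1/(2N)`` and ``1 - 1/(2N)``.
    """
    nt, nf = counts.n_targets, counts.n_foils
    if nt == 0 or nf == 0:
        raise ValueError("cannot form an ROC with zero targets or zero foils")
    # cumulative counts for categories 6, >=5, ..., >=2
    tc = np.asarray(counts.target_counts, float)
    fc = np.asarray(counts.foil_counts, float)
    h = np.cumsum(tc[::-1])[:N_CRITERIA] / nt
    fa = np.cumsum(fc[::-1])[:N_CRITERIA] / nf
    if zero_one_adjust:
        h = np.where(h <= 0, 1 / (2 * nt), np.where(h >= 1, 1 - 1 / (2 * nt), h))
        fa = np.where(fa <= 0, 1 / (2 * nf), np.where(fa >= 1, 1 - 1 / (2 * nf), fa))
        h = np.maximum.accumulate(h)
        fa = np.maximum.accumulate(fa)
    return ROCCurve(tuple(h), tuple(fa))


def dpsd_predict(params: DPSDParams):
    """Predicted cumulative (H_i, FA_i) under the DPSD model."""
    c = np.asarray(params.criteria, float)[::-1]  # strictest first
    h = params.R + (1 - params.R) * norm.cdf(params.dprime - c)
    fa = norm.cdf(-c)
    return h, fa


def dpsd_category_probs(params: DPSDParams):
    """Probability of each confidence category (1..6) for targets and foils."""
    h, fa = dpsd_predict(params)
    # h/fa are cumulative for categories 6, >=5, ..., >=2; category probs by differencing
    hc = np.concatenate([[0.0], h, [1.0]])
    fc = np.concatenate([[0.0], fa, [1.0]])
    p_t = np.diff(hc)[::-1]  # category 1..6
    p_f = np.diff(fc)[::-1]
    return np.clip(p_t, 0, 1), np.clip(p_f, 0, 1)


def zroc_slope(curve: ROCCurve) -> float:
    """Least-squares slope of the ROC in inverse-normal (z) coordinates.

    Equals 1 for data from an equal-variance SDT process (R = 0); the
    recollection threshold process pushes the slope below 1.
    """
    h = np.asarray(curve.hit_rates)
    fa = np.asarray(curve.fa_rates)
    if np.any((h <= 0) | (h >= 1) | (fa <= 0) | (fa >= 1)):
        raise ValueError("zROC requires rates strictly inside (0, 1); "
                         "use zero_one_adjust when cumulating")
    zh, zf = norm.ppf(h), norm.ppf(fa)
    slope = np.polyfit(zf, zh, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# fitting


def _pack(R, d, criteria):
    c = np.asarray(criteria, float)
    deltas = np.diff(c)
    return np.concatenate([[R, d, c[0]], np.log(np.maximum(deltas, 1e-6))])


def _unpack(x):
    R = float(np.clip(x[0], 0.0, 1.0))
    d = float(x[1])
    c = x[2] + np.concatenate([[0.0], np.cumsum(np.exp(x[3:]))])
    return R, d, c


def _informative(counts: ConfidenceCounts) -> bool:
    """At least two criteria separate mass for targets or foils."""
    def n_used(v):
        return int(np.count_nonzero(np.asarray(v)))
    return max(n_used(counts.target_counts), n_used(counts.foil_counts)) >= 2


class DPSDModel:
    """Dual-process signal-detection model for one condition's counts.

    Parameters
    ----------
    counts : ConfidenceCounts
    objective : {"sse", "mle"}
        ``sse`` minimises squared error on the five cumulative ROC points;
        ``mle`` minimises the multinomial negative log-likelihood over the
        six response categories for targets and foils jointly.
    zero_one_adjust : bool
        Replace observed cumulative proportions of exactly 0 or 1 by
        1/(2N) and 1−1/(2N).  Off by default for fitting: the SSE
        objective needs no inverse-normal transform, so raw proportions
        are usable as-is (matching the spreadsheet-style SSE fit).
    smooth : bool
        Add-half smoothing of category counts before cumulation.  On by
        default: empty extreme-confidence bins (common at 80 trials)
        otherwise push the fitted criteria outward and bias d' upward as
        recollection grows, and smoothing removes that small-sample
        pathology without affecting large-sample fits.
    """

    def __init__(self, counts: ConfidenceCounts, objective: str = "sse",
                 zero_one_adjust: bool = False, smooth: bool = True):
        if objective not in ("sse", "mle"):
            raise ValueError("objective must be 'sse' or 'mle'")
        self.counts = counts
        self.objective = objective
        self.zero_one_adjust = zero_one_adjust
        self.smooth = smooth
        tc = np.asarray(counts.target_counts, float)
        fc = np.asarray(counts.foil_counts, float)
        if smooth:
            tc = tc + 0.5
            fc = fc + 0.5
        self._tc, self._fc = tc, fc
        nt, nf = tc.sum(), fc.sum()
        h = np.cumsum(tc[::-1])[:N_CRITERIA] / nt
        fa = np.cumsum(fc[::-1])[:N_CRITERIA] / nf
        if zero_one_adjust:
            h = np.where(h <= 0, 1 / (2 * nt), np.where(h >= 1, 1 - 1 / (2 * nt), h))
            fa = np.where(fa <= 0, 1 / (2 * nf), np.where(fa >= 1, 1 - 1 / (2 * nf), fa))
            h = np.maximum.accumulate(h)
            fa = np.maximum.accumulate(fa)
        self._h_obs, self._fa_obs = h, fa

    # objective ------------------------------------------------------------
    def _objective_value(self, x) -> float:
        R, d, c = _unpack(x)
        cs = c[::-1]
        h = R + (1 - R) * ndtr(d - cs)
        fa = ndtr(-cs)
        if self.objective == "sse":
            return float(np.sum((self._h_obs - h) ** 2) + np.sum((self._fa_obs - fa) ** 2))
        hc = np.concatenate([[0.0], h, [1.0]])
        fc = np.concatenate([[0.0], fa, [1.0]])
        p_t = np.clip(np.diff(hc)[::-1], 1e-12, 1.0)
        p_f = np.clip(np.diff(fc)[::-1], 1e-12, 1.0)
        return float(-(self._tc @ np.log(p_t) + self._fc @ np.log(p_f)))

    def _sse_grad(self, x):
        """Analytic gradient of the SSE objective in the packed coordinates."""
        R, d, c = _unpack(x)
        cs = c[::-1]
        phi_t = norm.pdf(d - cs)
        Phi_t = ndtr(d - cs)
        rH = (R + (1 - R) * Phi_t) - self._h_obs
        rF = ndtr(-cs) - self._fa_obs
        dR = float(np.sum(2 * rH * (1 - Phi_t)))
        dd = float(np.sum(2 * rH * (1 - R) * phi_t))
        g_cs = -2 * (rH * (1 - R) * phi_t + rF * norm.pdf(cs))
        g_c = g_cs[::-1]  # back to increasing-criteria order
        grad = np.empty_like(x)
        grad[0], grad[1] = dR, dd
        grad[2] = g_c.sum()
        exp_u = np.exp(x[3:])
        for m in range(1, N_CRITERIA):
            grad[2 + m] = exp_u[m - 1] * g_c[m:].sum()
        return grad

    def _starts(self, restarts: int, seed):
        """Heuristic start plus seeded jitters."""
        fa = np.clip(self._fa_obs, 1e-3, 1 - 1e-3)
        h = np.clip(self._h_obs, 1e-3, 1 - 1e-3)
        c0 = np.sort(-norm.ppf(fa))  # increasing criteria from foil rates
        c0 = _strictify(c0)
        d0 = float(np.mean(norm.ppf(h) - norm.ppf(fa)))
        # intercept heuristic: excess of strictest hit rate over familiarity alone
        r0 = float(np.clip(h[0] - norm.cdf(d0 - c0[-1]), 0.0, 0.95))
        starts = [_pack(r0, d0, c0)]
        rng = substream(0 if seed is None else seed, "dpsd-restarts")
        for _ in range(max(0, restarts - 1)):
            rj = float(np.clip(rng.uniform(0, 0.8), 0, 1))
            dj = d0 + rng.normal(0, 0.7)
            cj = _strictify(np.sort(c0 + rng.normal(0, 0.4, size=N_CRITERIA)))
            starts.append(_pack(rj, dj, cj))
        return starts

    def fit(self, restarts: int = 10, seed=None) -> "DPSDResults":
        """Fit by multi-start bounded quasi-Newton minimisation."""
        if not _informative(self.counts):
            # all responses in one category: boundary fit, flagged
            params = DPSDParams(0.0, 0.0, (-1.2, -0.6, 0.0, 0.6, 1.2))
            x = _pack(params.R, params.dprime, params.criteria)
            return DPSDResults(self, params, self._objective_value(x),
                               converged=False, n_restarts=0)
        bounds = [(0.0, 1.0), (-5.0, 8.0), (-6.0, 6.0)] + [(-8.0, 3.0)] * (N_CRITERIA - 1)
        jac = self._sse_grad if self.objective == "sse" else None
        best = None
        n_same = 0
        for x0 in self._starts(restarts, seed):
            res = optimize.minimize(self._objective_value, x0, method="L-BFGS-B",
                                    jac=jac, bounds=bounds)
            if best is None or res.fun < best.fun - 1e-10:
                best, n_same = res, 0
            else:
                n_same += 1
            # repeated convergence to the same optimum: stop restarting early
            if n_same >= 2 and abs(res.fun - best.fun) < 1e-9:
                break
        R, d, c = _unpack(best.x)
        params = DPSDParams(R, d, tuple(_strictify(c)))
        return DPSDResults(self, params, float(best.fun),
                           converged=bool(best.success), n_restarts=restarts)


def _strictify(c, eps=1e-4):
    c = np.asarray(c, float).copy()
    for i in range(1, len(c)):
        if c[i] <= c[i - 1] + eps:
            c[i] = c[i - 1] + eps
    return c


@dataclass
class DPSDResults:
    """Fitted DPSD parameters with objective diagnostics."""

    model: DPSDModel
    params: DPSDParams
    objective_value: float
    converged: bool
    n_restarts: int

    @property
    def R(self) -> float:
        return self.params.R

    @property
    def dprime(self) -> float:
        return self.params.dprime

    def predict(self):
        return dpsd_predict(self.params)

    def plot_roc(self, ax=None):
        """Observed vs. fitted ROC (probability coordinates)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        h_pred, fa_pred = self.predict()
        ax.plot([0, 1], [0, 1], ":", color="0.6", lw=1)
        ax.plot(self.model._fa_obs, self.model._h_obs, "o", color="k",
                label="observed")
        grid = np.linspace(-4, 4, 200)
        h = self.params.R + (1 - self.params.R) * norm.cdf(self.params.dprime - grid)
        fa = norm.cdf(-grid)
        ax.plot(fa, h, "-", color="C0",
                label=f"DPSD fit (R={self.params.R:.2f}, d'={self.params.dprime:.2f})")
        ax.plot(fa_pred, h_pred, "x", color="C0", ms=6)
        ax.set_xlabel("false-alarm rate")
        ax.set_ylabel("hit rate")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.legend(loc="lower right", fontsize=8)
        return ax

    def summary(self) -> str:
        h, fa = self.predict()
        lines = [
            "Dual-process signal-detection fit",
            "=================================",
            f"objective       : {self.model.objective} = {self.objective_value:.6f}",
            f"converged       : {self.converged} ({self.n_restarts} restarts)",
            f"recollection R  : {self.params.R:.4f}",
            f"familiarity d'  : {self.params.dprime:.4f}",
            "criteria        : " + ", ".join(f"{c:.3f}" for c in self.params.criteria),
            "predicted H     : " + ", ".join(f"{x:.3f}" for x in h),
            "predicted FA    : " + ", ".join(f"{x:.3f}" for x in fa),
        ]
        return "\n".join(lines)


def dpsd_estimates(trials, objective: str = "sse", restarts: int = 10,
                   seed=None, zero_one_adjust: bool = False,
                   smooth: bool = True):
    """Fit the DPSD model per participant × material from a tidy trial table.

    Expects columns participant, group, material, item_status, confidence.
    Returns a DataFrame with R, d', criteria, objective and convergence.
    """
    import pandas as pd
    rows = []
    for i, ((pid, group, material), sub) in enumerate(trials.groupby(
            ["participant", "group", "material"], sort=True)):
        counts = ConfidenceCounts.from_trials(sub["confidence"], sub["item_status"])
        fit_seed = None if seed is None else (int(seed) * 1000 + i) % (2**31)
        res = fit_dpsd(counts, objective=objective, restarts=restarts,
                       seed=fit_seed, zero_one_adjust=zero_one_adjust,
                       smooth=smooth)
        row = {"participant": pid, "group": group, "material": material,
               "R": res.R, "dprime": res.dprime,
               "objective": res.objective_value,
               "objective_kind": objective, "converged": res.converged}
        for k, c in enumerate(res.params.criteria, start=1):
            row[f"c{k}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def fit_dpsd(counts: ConfidenceCounts, objective: str = "sse",
             restarts: int = 10, seed=None, zero_one_adjust: bool = False,
             smooth: bool = True) -> DPSDResults:
    """Convenience wrapper: build a :class:`DPSDModel` and fit it."""
    return DPSDModel(counts, objective=objective, zero_one_adjust=zero_one_adjust,
                     smooth=smooth).fit(restarts=restarts, seed=seed)
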