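"""Continuous brain–behavior inference: linear mixed models with Type-III
Satterthwaite F tests and Freedman–Lane permutation p-values.

The model predicts Z-scored memory performance from the fully factorial
fixed effects of a candidate ROI's bilateral volume Z-score, Process
(recollection vs. familiarity), Material-Type (faces vs. scenes) and
Paradigm (confidence-ROC vs. response-deadline), with per-participant
random effects: a random intercept, an uncorrelated random Process slope
in cross-process models (both process estimators induce negative
cross-process covariance within participant, which the Volume×Process test
must account for), and optionally uncorrelated Material-Type and Paradigm
slopes when a fit is singular.

All factors are sum-to-zero coded, so with 2-level factors each fixed
effect is a single coefficient and its Type-III test is the marginal Wald
F of that coefficient.  Denominator degrees of freedom use the
Satterthwaite approximation: for a contrast ``l``,

    df = 2 * (l' C(v) l)^2 / (g' A g)

where ``C(v) = (X' V(v)^{-1} X)^{-1}``, ``g`` is the gradient of
``l' C(v) l`` with respect to the variance components ``v``, and ``A`` is
the asymptotic covariance of the REML variance-component estimates
(inverse observed information).  Gradients and the information matrix are
obtained by central finite differences of the closed-form REML criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

from ._rng import substream

__all__ = ["VolumeLMM", "VolumeLMMResults", "fit_volume_lmm", "permutation_pvalues"]

DEFAULT_FORMULA = ("score_z ~ vol_z * C(process, Sum) * C(material, Sum)"
                   " * C(paradigm, Sum)")

_LABELS = {
    "vol_z": "Volume",
    "C(process, Sum)": "Process",
    "C(material, Sum)": "Material-Type",
    "C(paradigm, Sum)": "Paradigm",
    "age": "Age",
    "Intercept": "Intercept",
}


def _friendly(term: str) -> str:
    parts = []
    for p in term.split(":"):
        base = p.split("[")[0]
        parts.append(_LABELS.get(base, base))
    return "*".join(parts)


class _REMLEngine:
    """Closed-form REML for a grouped LMM with diagonal random effects."""

    def __init__(self, y, X, Z, group_idx):
        self.y = y
        self.X = X
        self.Z = Z  # (n, q) random-effect design; diagonal covariance
        self.groups = group_idx  # list of row-index arrays, one per group
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        # batch groups by size for vectorised per-group linear algebra
        self._batches = []
        by_size: dict = {}
        for idx in group_idx:
            by_size.setdefault(len(idx), []).append(idx)
        for ni, idxs in by_size.items():
            sel = np.array(idxs)  # (G, ni)
            self._batches.append((
                X[sel],            # (G, ni, p)
                Z[sel],            # (G, ni, q)
                y[sel],            # (G, ni)
                ni,
            ))

    def _assemble(self, v):
        """Return (logdet_sum, XtViX, XtViy, ytViy) at variance components v.

        v = (tau^2_1..q, sigma^2).
        """
        tau2 = np.asarray(v[:-1], float)
        sig2 = float(v[-1])
        p = self.p
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        ytViy = 0.0
        logdet = 0.0
        for X3, Z3, y2, ni in self._batches:
            V = sig2 * np.eye(ni)[None] + (Z3 * tau2) @ Z3.transpose(0, 2, 1)
            L = np.linalg.cholesky(V)  # raises LinAlgError if not PD
            logdet += 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
            rhs = np.concatenate([X3, y2[..., None]], axis=2)
            sol = np.linalg.solve(V, rhs)      # (G, ni, p+1)
            ViX, Viy = sol[..., :p], sol[..., p]
            XtViX += np.einsum("gip,giq->pq", X3, ViX)
            XtViy += np.einsum("gip,gi->p", X3, Viy)
            ytViy += float(np.einsum("gi,gi->", y2, Viy))
        return logdet, XtViX, XtViy, ytViy

    def reml(self, v) -> float:
        """REML log-likelihood (up to an additive constant)."""
        try:
            logdet, XtViX, XtViy, ytViy = self._assemble(v)
        except np.linalg.LinAlgError:
            return -np.inf
        sign, logdet_info = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - XtViy @ beta
        return -0.5 * (logdet + logdet_info + quad)

    def beta_cov(self, v):
        _, XtViX, XtViy, _ = self._assemble(v)
        C = np.linalg.inv(XtViX)
        beta = C @ XtViy
        return beta, C

    def fit(self, n_starts: int = 3, seed: int = 0):
        var_y = float(np.var(self.y)) or 1.0
        lo, hi = np.log(1e-8 * var_y), np.log(1e3 * var_y)
        bounds = [(lo, hi)] * (self.q + 1)

        def nll(w):
            val = self.reml(np.exp(w))
            return np.inf if not np.isfinite(val) else -val

        starts = [np.log(np.full(self.q + 1, var_y / (self.q + 1)))]
        rng = substream(seed, "lmm-starts")
        for _ in range(n_starts - 1):
            starts.append(np.clip(starts[0] + rng.normal(0, 1.5, self.q + 1), lo, hi))
        best = None
        for w0 in starts:
            res = optimize.minimize(nll, w0, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        v = np.exp(best.x)
        return v, -best.fun, bool(best.success)


@dataclass
class VolumeLMMResults:
    """Fitted mixed model with Type-III Satterthwaite inference."""

    model: "VolumeLMM"
    varcomps: np.ndarray        # (tau^2_1..q, sigma^2)
    loglike: float
    converged: bool
    singular: bool
    beta: np.ndarray
    cov_beta: np.ndarray
    fallback_from: "VolumeLMMResults | None" = None

    @property
    def fe_names(self):
        return self.model.fe_names

    def anova(self, effects=None) -> pd.DataFrame:
        """Type-III F tests with Satterthwaite denominator df.

        One row per fixed effect (intercept omitted); columns effect, df1,
        df2, F, p.  ``effects`` optionally restricts to friendly labels.
        """
        eng = self.model.engine
        v = self.varcomps
        # components at the optimizer's lower boundary carry no curvature info
        interior = v > 10 * 1e-8 * max(float(np.var(eng.y)), 1e-12)
        if not interior.any():
            interior = v == v.max()
        A = self._varcomp_cov(interior)
        rows = []
        for j, name in enumerate(self.fe_names):
            if name == "Intercept":
                continue
            label = _friendly(name)
            if effects is not None and label not in effects:
                continue
            f0 = self.cov_beta[j, j]
            g = self._grad_cjj(j, interior)
            denom = float(g @ A @ g)
            df2 = 2.0 * f0 ** 2 / denom if denom > 0 else np.inf
            df2 = float(min(max(df2, 1.0), eng.n - eng.p))
            F = float(self.beta[j] ** 2 / f0)
            p = float(stats.f.sf(F, 1, df2))
            rows.append({"effect": label, "df1": 1, "df2": df2, "F": F, "p": p})
        return pd.DataFrame(rows)

    # -- Satterthwaite internals -------------------------------------------
    def _grad_cjj(self, j, interior):
        eng = self.model.engine
        v = self.varcomps
        g = np.zeros(np.sum(interior))
        idxs = np.flatnonzero(interior)
        for out_i, k in enumerate(idxs):
            h = max(1e-4 * v[k], 1e-12)
            vp, vm = v.copy(), v.copy()
            vp[k] += h
            vm[k] = max(vm[k] - h, 1e-14)
            _, Cp = eng.beta_cov(vp)
            _, Cm = eng.beta_cov(vm)
            g[out_i] = (Cp[j, j] - Cm[j, j]) / (vp[k] - vm[k])
        return g

    def _varcomp_cov(self, interior):
        eng = self.model.engine
        v = self.varcomps
        idxs = np.flatnonzero(interior)
        k = len(idxs)
        H = np.zeros((k, k))
        steps = np.array([max(1e-3 * v[i], 1e-10) for i in idxs])

        def f(delta):
            vv = v.copy()
            vv[idxs] = np.maximum(vv[idxs] + delta, 1e-14)
            return eng.reml(vv)

        f0 = f(np.zeros(k))
        for a in range(k):
            ea = np.zeros(k)
            ea[a] = steps[a]
            H[a, a] = (f(ea) - 2 * f0 + f(-ea)) / steps[a] ** 2
            for b in range(a + 1, k):
                eb = np.zeros(k)
                eb[b] = steps[b]
                H[a, b] = H[b, a] = (
                    f(ea + eb) - f(ea - eb) - f(-ea + eb) + f(-ea - eb)
                ) / (4 * steps[a] * steps[b])
        info = -H
        try:
            A = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(info)
        # guard against a non-PD numerical Hessian
        w, Q = np.linalg.eigh(A)
        w = np.clip(w, 1e-14, None)
        return (Q * w) @ Q.T

    def plot_volume_scatter(self, by: str = "process", ax=None):
        """Participant-mean scores against ROI volume Z, one series per
        level of ``by`` with its least-squares line (the brain–behavior
        scatter that accompanies the mixed-model tests)."""
        import matplotlib.pyplot as plt
        data = self.model.data
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.5))
        dv = self.model.formula.split("~")[0].strip()
        for k, (level, sub) in enumerate(data.groupby(by)):
            agg = sub.groupby(self.model.groups_col).agg(
                y=(dv, "mean"), v=("vol_z", "first"))
            ax.plot(agg.v, agg.y, "o", color=f"C{k}", ms=4, label=str(level))
            b, a = np.polyfit(agg.v, agg.y, 1)
            xs = np.linspace(agg.v.min(), agg.v.max(), 2)
            ax.plot(xs, b * xs + a, "-", color=f"C{k}", lw=1)
        ax.set_xlabel("ROI volume (Z)")
        ax.set_ylabel(f"{dv} (participant mean)")
        ax.legend(fontsize=8)
        return ax

    def summary(self) -> str:
        lines = [
            "Linear mixed model (REML), Type III Satterthwaite",
            "=" * 49,
            f"observations : {self.model.engine.n}   groups : {len(self.model.engine.groups)}",
            f"random terms : {self.model.random_terms}",
            "var components: " + ", ".join(f"{x:.4g}" for x in self.varcomps)
            + "  (last = residual)",
            f"REML loglik  : {self.loglike:.3f}   singular: {self.singular}",
            "",
            self.anova().to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        if self.fallback_from is not None:
            lines.append("")
            lines.append("(refit with random Material-Type and Paradigm slopes "
                         "after a singular random-intercept fit)")
        return "\n".join(lines)


class VolumeLMM:
    """Mixed model of process scores on ROI volume (statsmodels-style).

    Parameters
    ----------
    data : DataFrame with columns used by ``formula`` plus the grouping
        column (default ``participant``).
    formula : patsy formula for the fixed effects (sum-coded factors).
    groups : grouping column for the random intercept.
    random_slopes : iterable of factor column names given uncorrelated
        random slopes (sum-coded), e.g. ("material", "paradigm").
    """

    def __init__(self, data: pd.DataFrame, formula: str = DEFAULT_FORMULA,
                 groups: str = "participant", random_slopes=()):
        data = data.dropna(subset=self._formula_vars(formula, data)).copy()
        self.data = data
        self.formula = formula
        self.groups_col = groups
        self.random_terms = ("intercept",) + tuple(random_slopes)
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        self.fe_names = list(X.columns)
        Xv = np.asarray(X, float)
        # degenerate fixed-effect design (e.g. constant volume) is an error
        if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
            raise ValueError("fixed-effect design is rank deficient "
                             "(e.g. constant volume Z across participants)")
        zcols = [np.ones(len(data))]
        for f in random_slopes:
            lv = sorted(data[f].unique())
            if len(lv) != 2:
                raise ValueError(f"random slope factor {f!r} must have 2 levels")
            zcols.append(np.where(data[f] == lv[0], 1.0, -1.0))
        Z = np.column_stack(zcols)
        gvals = data[groups].values
        order = {g: i for i, g in enumerate(pd.unique(gvals))}
        group_idx = [np.flatnonzero(gvals == g) for g in order]
        if len(group_idx) < 5:
            raise ValueError("need at least 5 participants")
        self.engine = _REMLEngine(np.asarray(y, float).ravel(), Xv, Z, group_idx)

    @staticmethod
    def _formula_vars(formula, data):
        names = []
        for col in data.columns:
            if col in formula:
                names.append(col)
        return names

    def fit(self, seed: int = 0, n_starts: int = 3) -> VolumeLMMResults:
        v, ll, ok = self.engine.fit(n_starts=n_starts, seed=seed)
        beta, C = self.engine.beta_cov(v)
        sig2 = v[-1]
        singular = bool(np.any(v[:-1] < 1e-4 * sig2))
        return VolumeLMMResults(self, v, ll, ok, singular, beta, C)


def fit_volume_lmm(table: pd.DataFrame, roi: str | None = None,
                   include_age: bool = False, random_slopes: str = "auto",
                   formula: str | None = None, dv: str = "score_z",
                   seed: int = 0) -> VolumeLMMResults:
    """Fit one ROI's Volume×Process×Material(-×Paradigm) mixed model.

    ``table`` is a long score table with a ``vol_z`` column (see
    ``inference.attach_volume``).  When Process is a within factor, the
    base covariance structure is a random intercept plus an uncorrelated
    random Process slope per participant: recollection and familiarity
    scores from the same data share estimation noise (the DPSD R/d'
    trade-off, the deadline subtraction), so cross-process covariances
    must be modelled for the Volume×Process test to be calibrated.
    Follow-up models within one process use a single random intercept.
    With ``random_slopes='auto'``, a singular base fit is refit adding
    uncorrelated random slopes for Material-Type and Paradigm; the
    returned results then carry the base fit in ``fallback_from``.
    """
    factors = [f for f in ("process", "material", "paradigm")
               if f in table.columns and table[f].nunique() > 1]
    if formula is None:
        rhs = " * ".join(["vol_z"] + [f"C({f}, Sum)" for f in factors])
        formula = f"{dv} ~ {rhs}"
    if include_age:
        formula += " + age"
    base_slopes = ("process",) if "process" in factors else ()
    base = VolumeLMM(table, formula=formula, random_slopes=base_slopes).fit(seed=seed)
    if base.singular and random_slopes == "auto":
        slope_factors = base_slopes + tuple(
            f for f in ("material", "paradigm") if f in factors)
        if len(slope_factors) > len(base_slopes):
            refit = VolumeLMM(table, formula=formula,
                              random_slopes=slope_factors).fit(seed=seed)
            refit.fallback_from = base
            return refit
    return base


def permutation_pvalues(results: VolumeLMMResults, n_perm: int = 5000,
                        seed: int = 0, effects=None) -> pd.DataFrame:
    """Freedman–Lane permutation p-values for the model's fixed effects.

    The data are whitened with the fitted marginal covariance (so rows are
    exchangeable to the model's accuracy); for each effect, residuals of
    the reduced model excluding that column are permuted, added back to the
    reduced fit, and the full-model F statistic is recomputed.
    p = (b + 1)/(n_perm + 1) where b counts permuted F >= observed F.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    eng = results.model.engine
    v = results.varcomps
    tau2, sig2 = v[:-1], v[-1]
    # block-diagonal V^{-1/2}
    Wy = np.empty_like(eng.y)
    WX = np.empty_like(eng.X)
    for idx in eng.groups:
        Zi = eng.Z[idx]
        Vi = sig2 * np.eye(len(idx)) + (Zi * tau2) @ Zi.T
        w, Q = np.linalg.eigh(Vi)
        Wi = (Q / np.sqrt(w)) @ Q.T
        Wy[idx] = Wi @ eng.y[idx]
        WX[idx] = Wi @ eng.X[idx]
    n, p = WX.shape
    C_full = np.linalg.inv(WX.T @ WX)
    B_full = C_full @ WX.T
    rng = substream(seed, "permutation")
    rows = []
    for j, name in enumerate(results.fe_names):
        if name == "Intercept":
            continue
        label = _friendly(name)
        if effects is not None and label not in effects:
            continue
        keep = [k for k in range(p) if k != j]
        Xr = WX[:, keep]
        Br = np.linalg.pinv(Xr)
        fit_r = Xr @ (Br @ Wy)
        resid_r = Wy - fit_r

        def fstat(Ymat):
            beta = B_full @ Ymat
            rss = np.sum((Ymat - WX @ beta) ** 2, axis=0)
            s2 = rss / (n - p)
            return beta[j] ** 2 / (C_full[j, j] * s2)

        F_obs = float(fstat(Wy[:, None])[0])
        perm = np.empty((n, n_perm))
        for b in range(n_perm):
            perm[:, b] = resid_r[rng.permutation(n)]
        F_perm = fstat(fit_r[:, None] + perm)
        b_ge = int(np.sum(F_perm >= F_obs))
        rows.append({"effect": label, "F": F_obs,
                     "p_perm": (b_ge + 1) / (n_perm + 1)})
    return pd.DataFrame(rows)
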