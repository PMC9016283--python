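"""Statistical machinery for the patient/control comparisons.

Covers the categorical analysis path: Z-transforming behavioral scores
against control norms, multiple imputation of missing control scores by
chained equations, mixed between×within repeated-measures ANOVAs (with the
range of F and p reported across imputations), follow-up simple effects,
and the simple demographic tests (Pearson chi-square without continuity
correction, Mann–Whitney U).

The mixed ANOVA uses the per-participant contrast-score reduction: with
2-level within factors, every within effect corresponds to one contrast
over a participant's cell means, and the between-group test of that effect
is a one-way ANOVA on the contrast scores.  For a design with g groups and
N participants this yields F(g−1, N−g) tests, matching classical
mixed-model ANOVA output for such designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_seed

__all__ = [
    "ImputationConfig",
    "Chi2Result",
    "MannWhitneyResult",
    "build_long_scores",
    "attach_volume",
    "zscore_behavior",
    "impute_chained",
    "mixed_anova",
    "mixed_anova_mi",
    "simple_effects",
    "pearson_chi2",
    "mann_whitney_u",
]

WITHIN_FACTORS = ("process", "material", "paradigm")


# ---------------------------------------------------------------------------
# long-table assembly


def build_long_scores(dpsd_estimates: pd.DataFrame,
                      rdp_estimates: pd.DataFrame) -> pd.DataFrame:
    """Tidy (participant, group, process, material, paradigm, score) table.

    The confidence-ROC paradigm contributes recollection = fitted R and
    familiarity = fitted d'; the deadline paradigm contributes its
    subtraction-based estimates.
    """
    rows = []
    for rec in dpsd_estimates.itertuples(index=False):
        rows.append({"participant": rec.participant, "group": rec.group,
                     "material": rec.material, "paradigm": "ROC",
                     "process": "recollection", "score": rec.R})
        rows.append({"participant": rec.participant, "group": rec.group,
                     "material": rec.material, "paradigm": "ROC",
                     "process": "familiarity", "score": rec.dprime})
    for rec in rdp_estimates.itertuples(index=False):
        rows.append({"participant": rec.participant, "group": rec.group,
                     "material": rec.material, "paradigm": "RDP",
                     "process": "recollection", "score": rec.recollection})
        rows.append({"participant": rec.participant, "group": rec.group,
                     "material": rec.material, "paradigm": "RDP",
                     "process": "familiarity", "score": rec.familiarity})
    long = pd.DataFrame(rows)
    dups = long.duplicated(["participant", "process", "material", "paradigm"])
    if dups.any():
        raise ValueError("duplicate (participant, process, material, paradigm) rows")
    return long


def attach_volume(long: pd.DataFrame, zvols: pd.DataFrame, roi: str,
                  hemisphere: str = "bilateral",
                  participants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join one ROI's volume Z-scores (and optionally age) onto the table."""
    sel = zvols[(zvols["roi"] == roi) & (zvols["hemisphere"] == hemisphere)]
    sel = sel[["participant", "z"]].rename(columns={"z": "vol_z"})
    out = long.merge(sel, on="participant", how="left")
    if participants is not None:
        out = out.merge(participants[["participant", "age"]], on="participant",
                        how="left")
    return out


# ---------------------------------------------------------------------------
# behavioral Z-scoring


def zscore_behavior(long: pd.DataFrame,
                    control_group: str = "control_behavior") -> pd.DataFrame:
    """Z-transform scores against the control mean and SD per design cell.

    Controls with missing values in a cell are excluded cell-wise.  Returns
    a copy with a ``score_z`` column (controls are Z-scored against their
    own norms too, so their cell mean is 0 by construction).
    """
    out = long.copy()
    out["score_z"] = np.nan
    for key, idx in out.groupby(list(WITHIN_FACTORS)).groups.items():
        cell = out.loc[idx]
        ctrl = cell[cell["group"] == control_group]["score"].dropna()
        if len(ctrl) < 2:
            raise ValueError(f"cell {key}: need >= 2 observed controls")
        m, s = ctrl.mean(), ctrl.std(ddof=1)
        if s == 0:
            raise ValueError(f"cell {key}: zero control variance")
        out.loc[idx, "score_z"] = (cell["score"] - m) / s
    return out


# ---------------------------------------------------------------------------
# multiple imputation


@dataclass
class ImputationConfig:
    m: int = 5
    method: str = "pmm"       # or "normal"
    seed: int = 0
    max_iterations: int = 10

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least m=2 imputations")
        if self.method not in ("pmm", "normal"):
            raise ValueError("method must be 'pmm' or 'normal'")


def impute_chained(wide: pd.DataFrame, config: ImputationConfig | None = None) -> list:
    """Multiple imputation by chained equations on a wide numeric table.

    Returns ``m`` completed copies; observed cells are never altered.
    Default method is predictive mean matching (10 chained iterations per
    imputation); ``normal`` uses Bayesian-ridge chained regression with
    posterior sampling.
    """
    config = config or ImputationConfig()
    numeric = wide.select_dtypes(include=[np.number])
    meta = wide.drop(columns=numeric.columns)
    if numeric.isna().all().any():
        bad = numeric.columns[numeric.isna().all()].tolist()
        raise ValueError(f"variables with all values missing: {bad}")
    frac = numeric.isna().mean()
    if (frac >= 0.5).any():
        bad = frac[frac >= 0.5].index.tolist()
        raise ValueError(f"missingness >= 50% for: {bad}")
    if not numeric.isna().any().any():
        return [wide.copy() for _ in range(config.m)]

    completed = []
    if config.method == "pmm":
        from statsmodels.imputation.mice import MICEData
        state = np.random.get_state()
        try:
            np.random.seed(child_seed(config.seed, "mice"))
            md = MICEData(numeric.reset_index(drop=True))
            for _ in range(config.m):
                md.update_all(config.max_iterations)
                filled = md.data.copy()
                filled.index = numeric.index
                completed.append(filled)
        finally:
            np.random.set_state(state)
    else:
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
        for i in range(config.m):
            imp = IterativeImputer(sample_posterior=True,
                                   max_iter=config.max_iterations,
                                   random_state=child_seed(config.seed, "mice", i))
            filled = pd.DataFrame(imp.fit_transform(numeric),
                                  columns=numeric.columns, index=numeric.index)
            completed.append(filled)

    out = []
    for filled in completed:
        # guarantee observed cells are untouched
        filled = filled.where(numeric.isna(), numeric)
        out.append(pd.concat([meta, filled], axis=1)[wide.columns])
    return out


# ---------------------------------------------------------------------------
# mixed between x within ANOVA


def _cell_matrix(table: pd.DataFrame, dv: str, subject: str, within: tuple):
    """Per-subject complete cell matrix and ±1 codes per within factor."""
    levels = {}
    for f in within:
        lv = sorted(table[f].unique())
        if len(lv) != 2:
            raise ValueError(f"within factor {f!r} must have exactly 2 levels, "
                             f"got {lv}")
        levels[f] = lv
    wide = table.pivot_table(index=subject, columns=list(within), values=dv,
                             aggfunc="first", dropna=False)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"unbalanced within-design (missing cells) for {missing}")
    groups = table.groupby(subject).agg(_g=("group", "first"))["_g"] \
        if "group" in table.columns else None
    return wide, levels


def _contrast_scores(wide: pd.DataFrame, within: tuple, effect: tuple, levels: dict):
    """Per-subject contrast score for a within effect (empty = grand mean)."""
    cols = wide.columns  # MultiIndex over within levels (or plain for 1 factor)
    codes = np.ones(len(cols))
    for f in effect:
        fi = within.index(f)
        lv = levels[f]
        if len(within) == 1:
            vals = np.asarray([c for c in cols])
        else:
            vals = np.asarray([c[fi] for c in cols])
        codes *= np.where(vals == lv[0], 1.0, -1.0)
    return wide.values @ (codes / len(cols))


def _oneway(scores: np.ndarray, grp: np.ndarray):
    """One-way ANOVA; safe at zero within-group variance."""
    glevels = sorted(pd.unique(grp))
    n = len(scores)
    g = len(glevels)
    grand = scores.mean()
    ssb = sum(((scores[grp == lv].mean() - grand) ** 2) * (grp == lv).sum()
              for lv in glevels)
    ssw = sum(((scores[grp == lv] - scores[grp == lv].mean()) ** 2).sum()
              for lv in glevels)
    df1, df2 = g - 1, n - g
    if df2 <= 0:
        raise ValueError("not enough participants for a between-group test")
    msb, msw = ssb / df1, ssw / df2
    if msw == 0:
        F = 0.0 if msb == 0 else np.inf
    else:
        F = msb / msw
    p = 1.0 if F == 0 else float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return float(F), df1, df2, float(min(max(p, np.nextafter(0, 1)), 1.0))


def _effect_label(effect: tuple) -> str:
    parts = ["Group"] + [f.capitalize() for f in effect]
    return "*".join(parts)


def mixed_anova(table: pd.DataFrame, dv: str = "score",
                subject: str = "participant", between: str = "group",
                within: tuple = WITHIN_FACTORS) -> pd.DataFrame:
    """Between-group tests for a mixed repeated-measures design.

    Reports the between-group main effect and every Group×(within effect)
    interaction, one row per effect with columns effect, df1, df2, F, p.
    """
    within = tuple(within)
    wide, levels = _cell_matrix(table, dv, subject, within)
    grp = table.groupby(subject)[between].first().loc[wide.index].values
    rows = []
    effects = [()] + [e for r in range(1, len(within) + 1)
                      for e in combinations(within, r)]
    for effect in effects:
        scores = _contrast_scores(wide, within, effect, levels)
        F, df1, df2, p = _oneway(scores, grp)
        rows.append({"effect": _effect_label(effect), "df1": df1, "df2": df2,
                     "F": F, "p": p})
    return pd.DataFrame(rows)


def mixed_anova_mi(tables, dv: str = "score", subject: str = "participant",
                   between: str = "group",
                   within: tuple = WITHIN_FACTORS) -> pd.DataFrame:
    """Mixed ANOVA across imputed datasets: per-effect min/max of F and p."""
    per = [mixed_anova(t, dv, subject, between, within) for t in tables]
    out = per[0][["effect", "df1", "df2"]].copy()
    Fs = np.array([t["F"].values for t in per])
    ps = np.array([t["p"].values for t in per])
    out["F_min"] = Fs.min(axis=0)
    out["F_max"] = Fs.max(axis=0)
    out["p_min"] = ps.min(axis=0)
    out["p_max"] = ps.max(axis=0)
    return out


def simple_effects(table: pd.DataFrame, split_by: str, dv: str = "score",
                   subject: str = "participant", between: str = "group",
                   within: tuple = WITHIN_FACTORS) -> pd.DataFrame:
    """Follow-up between-group tests at each level of one within factor."""
    within = tuple(within)
    if split_by not in within:
        raise ValueError(f"{split_by!r} is not a within factor")
    lv = sorted(table[split_by].unique())
    if len(lv) < 2:
        raise ValueError(f"cannot split on constant factor {split_by!r}")
    remaining = tuple(f for f in within if f != split_by)
    rows = []
    for level in lv:
        sub = table[table[split_by] == level]
        res = mixed_anova(sub, dv, subject, between, remaining)
        grp_row = res[res["effect"] == "Group"].iloc[0]
        rows.append({"level": level, "effect": "Group", "df1": grp_row["df1"],
                     "df2": grp_row["df2"], "F": grp_row["F"], "p": grp_row["p"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demographic tests


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float


def pearson_chi2(table) -> Chi2Result:
    """Pearson chi-square of independence, no continuity correction."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("need a 2-D nonnegative count table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("empty row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return Chi2Result(float(chi2), int(df), float(p))


def mann_whitney_u(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney test, U from the smaller sample's rank sum.

    With fully separated samples U is 0 when the smaller sample ranks
    uniformly lower and n1*n2 when it ranks uniformly higher.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    small, large = (x, y) if len(x) <= len(y) else (y, x)
    res = stats.mannwhitneyu(small, large, alternative="two-sided")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))
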