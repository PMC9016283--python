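"""Categorical inference: Z-scoring, imputation, mixed ANOVA, simple tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from dualproc.inference import (
    ImputationConfig,
    impute_chained,
    mann_whitney_u,
    mixed_anova,
    mixed_anova_mi,
    pearson_chi2,
    simple_effects,
    zscore_behavior,
)


# ---------------------------------------------------------------------------
# Pearson chi-square (no continuity correction)


class TestPearsonChi2:
    def test_sex_ratio_table(self):
        # 9 patients (7M:2F) vs 48 volumetric controls (23M:25F)
        res = pearson_chi2([[7, 2], [23, 25]])
        assert res.chi2 == pytest.approx(2.71, abs=0.005)
        assert res.df == 1

    def test_deadline_session_sex_table(self):
        # face stimuli per deadline session: 20M:40F vs 19M:41F
        res = pearson_chi2([[20, 40], [19, 41]])
        assert res.chi2 == pytest.approx(0.038, abs=0.0005)

    def test_scene_theme_table(self):
        short = [3, 4, 3, 5, 5, 5, 4, 5, 7, 4, 5, 7, 3]
        long = [3, 5, 2, 5, 4, 5, 5, 4, 8, 4, 5, 7, 3]
        res = pearson_chi2([short, long])
        assert res.chi2 == pytest.approx(0.711, abs=0.0005)
        assert res.df == 12

    def test_identical_rows_give_zero(self):
        assert pearson_chi2([[5, 10, 15], [5, 10, 15]]).chi2 == pytest.approx(0.0)

    def test_invariant_to_permutation_and_transposition(self):
        t = np.array([[7, 2, 4], [23, 25, 9]])
        base = pearson_chi2(t).chi2
        assert pearson_chi2(t[:, [2, 0, 1]]).chi2 == pytest.approx(base)
        assert pearson_chi2(t[[1, 0]]).chi2 == pytest.approx(base)
        assert pearson_chi2(t.T).chi2 == pytest.approx(base)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [1, 2]])


class TestMannWhitney:
    def test_symmetric_samples_give_half_umax(self):
        x = [1.0, 3.0, 5.0, 7.0]
        y = [2.0, 4.0, 6.0, 8.0]
        res = mann_whitney_u(x, y)
        # near-perfect interleaving: U close to n1*n2/2
        assert abs(res.U - 8.0) <= 2

    def test_full_separation_is_orientation_dependent(self):
        low = [1.0, 2.0, 3.0]
        high = [10.0, 11.0, 12.0, 13.0]
        # U is computed from the smaller sample's rank sum: 0 when that
        # sample ranks uniformly lower, n1*n2 when uniformly higher
        assert mann_whitney_u(low, high).U == 0.0
        assert mann_whitney_u(high, low).U == 0.0
        assert mann_whitney_u([10.0, 11.0, 12.0], [1.0, 2.0, 3.0, 4.0]).U == 12.0

    def test_small_sample_p_matches_enumeration(self):
        """Exact two-sided p for n1=n2=3 agrees with brute-force enumeration
        over all 20 assignments of ranks to the first sample."""
        x = [1.1, 2.5, 0.3]
        y = [3.0, 4.2, 2.9]
        res = mann_whitney_u(x, y)
        pooled = np.array(x + y)
        ranks = rankdata(pooled)
        obs_u = sum(1 for xi in x for yi in y if xi > yi)
        us = []
        for combo in itertools.combinations(range(6), 3):
            rx = ranks[list(combo)]
            u = rx.sum() - 3 * 4 / 2
            us.append(u)
        us = np.array(us)
        # two-sided exact p: distance from the null mean n1*n2/2 = 4.5
        p_exact = np.mean(np.abs(us - 4.5) >= abs(obs_u - 4.5))
        assert res.p == pytest.approx(p_exact, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# behavioral Z-scoring


def _long_table(scores_by_group):
    rows = []
    for grp, participants in scores_by_group.items():
        for pid, score_fn in participants:
            for pr in ("recollection", "familiarity"):
                for ma in ("faces", "scenes"):
                    for pa in ("ROC", "RDP"):
                        rows.append(dict(participant=pid, group=grp, process=pr,
                                         material=ma, paradigm=pa,
                                         score=score_fn(pr, ma, pa)))
    return pd.DataFrame(rows)


class TestZscoreBehavior:
    def test_patient_at_control_mean_scores_zero(self):
        table = _long_table({
            "control_behavior": [(f"C{i}", lambda *a, v=v: v)
                                 for i, v in enumerate([1.0, 2.0, 3.0])],
            "patient": [("P1", lambda *a: 2.0)],
        })
        z = zscore_behavior(table)
        assert (z.loc[z.participant == "P1", "score_z"] == 0).all()

    def test_one_sd_below_scores_minus_one(self):
        table = _long_table({
            "control_behavior": [(f"C{i}", lambda *a, v=v: v)
                                 for i, v in enumerate([1.0, 2.0, 3.0])],
            "patient": [("P1", lambda *a: 1.0)],  # mean 2, sd 1
        })
        z = zscore_behavior(table)
        assert (z.loc[z.participant == "P1", "score_z"] == -1.0).all()

    def test_planted_familiarity_deficit_recovered(self):
        rng = np.random.default_rng(3)
        ctr = [(f"C{i}", lambda *a: rng.normal(0, 1)) for i in range(40)]
        pats = [(f"P{i}", lambda pr, ma, pa: rng.normal(
            -1.5 if pr == "familiarity" else 0.0, 1)) for i in range(40)]
        z = zscore_behavior(_long_table({"control_behavior": ctr, "patient": pats}))
        pat = z[z.group == "patient"]
        fam = pat[pat.process == "familiarity"]["score_z"].mean()
        rec = pat[pat.process == "recollection"]["score_z"].mean()
        assert fam == pytest.approx(-1.5, abs=0.3)
        assert rec == pytest.approx(0.0, abs=0.3)

    def test_zero_control_variance_rejected(self):
        table = _long_table({
            "control_behavior": [(f"C{i}", lambda *a: 1.0) for i in range(3)],
            "patient": [("P1", lambda *a: 2.0)],
        })
        with pytest.raises(ValueError):
            zscore_behavior(table)


# ---------------------------------------------------------------------------
# multiple imputation


class TestImputeChained:
    @staticmethod
    def _wide(n=30, missing=0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({
            "a": x + rng.normal(0, 0.5, n),
            "b": 0.8 * x + rng.normal(0, 0.5, n),
            "c": -0.5 * x + rng.normal(0, 0.5, n),
        })
        if missing:
            idx = rng.choice(n, missing, replace=False)
            df.loc[idx, "a"] = np.nan
        return df

    def test_complete_data_returns_identical_copies(self):
        wide = self._wide()
        out = impute_chained(wide, ImputationConfig(m=5, seed=1))
        assert len(out) == 5
        for t in out:
            pd.testing.assert_frame_equal(t, wide)

    def test_observed_cells_never_altered(self):
        wide = self._wide(missing=6)
        out = impute_chained(wide, ImputationConfig(m=3, seed=1))
        mask = wide.notna()
        for t in out:
            assert t.notna().all().all()
            pd.testing.assert_frame_equal(t.where(mask), wide.where(mask))

    def test_same_seed_reproduces_imputations(self):
        wide = self._wide(missing=6)
        a = impute_chained(wide, ImputationConfig(m=3, seed=42))
        b = impute_chained(wide, ImputationConfig(m=3, seed=42))
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    @pytest.mark.parametrize("method", ["pmm", "normal"])
    def test_mcar_pooled_mean_unbiased(self, method):
        """20% MCAR deletion: pooled imputed mean within 2 MC SEs of the
        complete-data mean."""
        full = self._wide(n=100, seed=5)
        target = full["a"].mean()
        wide = full.copy()
        rng = np.random.default_rng(6)
        wide.loc[rng.choice(100, 20, replace=False), "a"] = np.nan
        out = impute_chained(wide, ImputationConfig(m=5, seed=7, method=method))
        pooled = np.mean([t["a"].mean() for t in out])
        se = full["a"].std() / np.sqrt(100)
        assert pooled == pytest.approx(target, abs=2 * se)

    def test_all_missing_variable_rejected(self):
        wide = self._wide()
        wide["a"] = np.nan
        with pytest.raises(ValueError):
            impute_chained(wide, ImputationConfig(seed=0))


# ---------------------------------------------------------------------------
# mixed between x within ANOVA


# Frozen from R: aov(score ~ group*process*material*paradigm +
#   Error(participant/(process*material*paradigm))) on the anova_fixture data.
R_AOV_EXPECTED = {
    "Group": (7.288, 0.0182),
    "Group*Process": (4.102, 0.0639),
    "Group*Material": (0.228, 0.6413),
    "Group*Paradigm": (2.765, 0.1202),
    "Group*Process*Material": (2.162, 0.1652),
    "Group*Process*Paradigm": (0.672, 0.4272),
    "Group*Material*Paradigm": (0.412, 0.5320),
    "Group*Process*Material*Paradigm": (13.534, 0.0028),
}


class TestMixedAnova:
    def test_matches_r_aov_reference(self, anova_fixture):
        res = mixed_anova(anova_fixture).set_index("effect")
        for effect, (F, p) in R_AOV_EXPECTED.items():
            assert res.loc[effect, "F"] == pytest.approx(F, abs=0.002), effect
            assert res.loc[effect, "p"] == pytest.approx(p, abs=0.0002), effect
            assert res.loc[effect, "df1"] == 1
            assert res.loc[effect, "df2"] == 13  # 15 participants - 2 groups

    def test_zero_noise_zero_difference_gives_f_zero(self):
        rows = []
        for i, grp in enumerate(["A"] * 4 + ["B"] * 4):
            for pr in ("recollection", "familiarity"):
                for ma in ("faces", "scenes"):
                    for pa in ("ROC", "RDP"):
                        rows.append(dict(participant=f"S{i}", group=grp,
                                         process=pr, material=ma, paradigm=pa,
                                         score=1.0 if pr == "recollection" else 0.5))
        res = mixed_anova(pd.DataFrame(rows)).set_index("effect")
        assert res.loc["Group", "F"] == 0.0
        assert res.loc["Group", "p"] == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(11)
        rows = []
        for i, grp in enumerate(["A"] * 10 + ["B"] * 10):
            shift = 2.0 if grp == "B" else 0.0
            for pr in ("recollection", "familiarity"):
                for ma in ("faces", "scenes"):
                    for pa in ("ROC", "RDP"):
                        rows.append(dict(participant=f"S{i}", group=grp,
                                         process=pr, material=ma, paradigm=pa,
                                         score=shift + rng.normal(0, 1)))
        res = mixed_anova(pd.DataFrame(rows)).set_index("effect")
        assert res.loc["Group", "p"] < 0.001

    def test_unbalanced_cells_rejected(self, anova_fixture):
        broken = anova_fixture.iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(broken)

    def test_single_case_group_supported(self, anova_fixture):
        """A single patient vs a control group (the single-case design)."""
        sub = anova_fixture[anova_fixture.participant.isin(
            [f"S{i:02d}" for i in range(7)])]
        res = mixed_anova(sub).set_index("effect")
        assert res.loc["Group", "df2"] == 5  # 7 participants - 2


class TestMixedAnovaMI:
    def test_identical_imputations_have_zero_p_range(self, anova_fixture):
        res = mixed_anova_mi([anova_fixture] * 5)
        assert np.allclose(res["p_min"], res["p_max"])
        assert np.allclose(res["F_min"], res["F_max"])

    def test_range_covers_each_imputation(self, anova_fixture):
        jitter = anova_fixture.copy()
        rng = np.random.default_rng(0)
        jitter["score"] = jitter["score"] + rng.normal(0, 0.05, len(jitter))
        res = mixed_anova_mi([anova_fixture, jitter])
        assert (res["p_min"] <= res["p_max"]).all()
        single = mixed_anova(anova_fixture)
        assert ((res["p_min"] <= single["p"].values + 1e-12)
                & (single["p"].values <= res["p_max"] + 1e-12)).all()


class TestSimpleEffects:
    def test_planted_process_specific_deficit(self):
        rng = np.random.default_rng(22)
        rows = []
        for i, grp in enumerate(["CTR"] * 12 + ["PAT"] * 12):
            b = rng.normal(0, 0.2)
            for pr in ("recollection", "familiarity"):
                deficit = -1.5 if (grp == "PAT" and pr == "familiarity") else 0.0
                for ma in ("faces", "scenes"):
                    for pa in ("ROC", "RDP"):
                        rows.append(dict(participant=f"S{i}", group=grp,
                                         process=pr, material=ma, paradigm=pa,
                                         score=b + deficit + rng.normal(0, 0.5)))
        res = simple_effects(pd.DataFrame(rows), split_by="process").set_index("level")
        assert res.loc["familiarity", "p"] < 0.001
        assert res.loc["recollection", "p"] > 0.05

    def test_constant_factor_rejected(self, anova_fixture):
        sub = anova_fixture[anova_fixture.process == "recollection"]
        with pytest.raises(ValueError):
            simple_effects(sub, split_by="process")
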