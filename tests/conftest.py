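"""Shared fixtures: deterministic synthetic data used across test modules."""

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def lmm_fixture():
    """Deterministic mixed-design dataset with a planted recollection slope.

    Expected values for this exact dataset were computed once with
    R lmerTest (Satterthwaite Type-III ANOVA) and are frozen in the tests
    that use it.
    """
    rng = np.random.default_rng(123)
    rows = []
    for i in range(12):
        vol = rng.normal(0, 1)
        b = rng.normal(0, 0.6)
        for process in ("recollection", "familiarity"):
            for material in ("faces", "scenes"):
                for paradigm in ("ROC", "RDP"):
                    mu = 0.2 + (0.8 * vol if process == "recollection" else 0.1 * vol)
                    y = mu + b + rng.normal(0, 0.5)
                    rows.append(dict(participant=f"P{i:02d}", vol_z=vol,
                                     process=process, material=material,
                                     paradigm=paradigm, score_z=y))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def anova_fixture():
    """Two-group mixed design (6 vs 9 participants, 2x2x2 within cells).

    Expected F values were computed once with R's aov using an
    Error(participant/(process*material*paradigm)) stratification and are
    frozen in the mixed-ANOVA tests.
    """
    rng = np.random.default_rng(77)
    rows = []
    for i, grp in enumerate(["A"] * 6 + ["B"] * 9):
        b = rng.normal(0, 0.5) + (0.7 if grp == "B" else 0)
        for pr in ("recollection", "familiarity"):
            for ma in ("faces", "scenes"):
                for pa in ("ROC", "RDP"):
                    y = b + (0.4 if (grp == "B" and pr == "recollection") else 0) \
                        + rng.normal(0, 0.4)
                    rows.append(dict(participant=f"S{i:02d}", group=grp,
                                     process=pr, material=ma, paradigm=pa,
                                     score=y))
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-design cohort (9 patients) generated once per session."""
    from dualproc.cohort import CohortSpec, generate_cohort
    return generate_cohort(CohortSpec(seed=11))
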