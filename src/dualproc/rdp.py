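"""Response-deadline procedure (RDP) estimation of familiarity and recollection.

The RDP rests on the selective reliance of recognition on the fast
familiarity signal when responses are forced at a short deadline, whereas a
long deadline additionally admits the slower recollection process.  With
equal-variance SDT discriminability d' computed per deadline,

    familiarity  = d'(short)
    recollection = d'(long) - d'(short)

Negative recollection estimates (sampling noise) are retained unclipped so
that group statistics remain unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import norm

__all__ = [
    "BinaryRecognitionCounts",
    "SDTEstimate",
    "ProcessEstimates",
    "dprime_from_counts",
    "estimate_processes",
    "counts_from_trials",
    "rdp_estimates",
]


@dataclass(frozen=True)
class BinaryRecognitionCounts:
    """Old/new outcome tallies for one deadline condition.

    Only responses made inside the response window are counted; trials with
    no in-window response carry no decision and are excluded from both
    numerator and denominator.
    """

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    deadline: str = "short"

    def __post_init__(self):
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.deadline not in ("short", "long"):
            raise ValueError("deadline must be 'short' or 'long'")

    @property
    def n_targets(self) -> int:
        return self.hits + self.misses

    @property
    def n_foils(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SDTEstimate:
    hit_rate: float
    fa_rate: float
    dprime: float
    correction: str
    deadline: str = "short"


@dataclass(frozen=True)
class ProcessEstimates:
    familiarity: float
    recollection: float
    short_dprime: float
    long_dprime: float


def dprime_from_counts(counts: BinaryRecognitionCounts,
                       correction: str = "loglinear") -> SDTEstimate:
    """Equal-variance SDT d' = z(hit rate) − z(false-alarm rate).

    correction : {"loglinear", "clamp"}
        ``loglinear`` adds 0.5 to each cell and 1 to each denominator
        before forming rates (applied to every estimate, so small-count
        conditions are treated uniformly); ``clamp`` replaces rates of
        exactly 0 or 1 by 1/(2N) and 1 − 1/(2N).
    """
    nt, nf = counts.n_targets, counts.n_foils
    if nt == 0 or nf == 0:
        raise ValueError("need at least one target and one foil trial")
    if correction == "loglinear":
        hr = (counts.hits + 0.5) / (nt + 1)
        far = (counts.false_alarms + 0.5) / (nf + 1)
    elif correction == "clamp":
        hr = counts.hits / nt
        far = counts.false_alarms / nf
        hr = min(max(hr, 1 / (2 * nt)), 1 - 1 / (2 * nt))
        far = min(max(far, 1 / (2 * nf)), 1 - 1 / (2 * nf))
    else:
        raise ValueError("correction must be 'loglinear' or 'clamp'")
    d = float(norm.ppf(hr) - norm.ppf(far))
    return SDTEstimate(float(hr), float(far), d, correction, counts.deadline)


def estimate_processes(short: SDTEstimate, long: SDTEstimate) -> ProcessEstimates:
    """Familiarity = short-deadline d'; recollection = long d' − short d'."""
    if short.deadline != "short" or long.deadline != "long":
        raise ValueError("estimates must come from the short and long "
                         "deadline conditions respectively")
    return ProcessEstimates(
        familiarity=short.dprime,
        recollection=long.dprime - short.dprime,
        short_dprime=short.dprime,
        long_dprime=long.dprime,
    )


def counts_from_trials(trials: pd.DataFrame, deadline: str) -> BinaryRecognitionCounts:
    """Tally one deadline condition from tidy trial rows.

    Expects columns ``deadline`` ∈ {short, long}, ``item_status`` ∈
    {target, foil}, ``response`` ∈ {old, new}; rows whose response is
    missing (no in-window response) are dropped.
    """
    sub = trials[trials["deadline"] == deadline]
    sub = sub[sub["response"].isin(["old", "new"])]
    t = sub[sub["item_status"] == "target"]
    f = sub[sub["item_status"] == "foil"]
    return BinaryRecognitionCounts(
        hits=int((t["response"] == "old").sum()),
        misses=int((t["response"] == "new").sum()),
        false_alarms=int((f["response"] == "old").sum()),
        correct_rejections=int((f["response"] == "new").sum()),
        deadline=deadline,
    )


def rdp_estimates(trials: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """Per participant × material process estimates from an RDP trial table."""
    rows = []
    for (pid, group, material), sub in trials.groupby(
            ["participant", "group", "material"], sort=True):
        short = dprime_from_counts(counts_from_trials(sub, "short"), correction)
        long = dprime_from_counts(counts_from_trials(sub, "long"), correction)
        est = estimate_processes(short, long)
        rows.append({
            "participant": pid, "group": group, "material": material,
            "familiarity": est.familiarity, "recollection": est.recollection,
            "short_dprime": est.short_dprime, "long_dprime": est.long_dprime,
            "correction": correction,
        })
    return pd.DataFrame(rows)
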