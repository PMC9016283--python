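"""Synthetic patient/control cohort generator with known ground truth.

The generator emulates the design of a two-paradigm recognition-memory
study in medial-temporal-lobe patients:

* a confidence-rating paradigm (80 targets + 80 foils per material, 6-point
  scale) whose responses are drawn from the dual-process signal-detection
  (DPSD) generative model, and
* a response-deadline paradigm (30 targets + 30 foils per deadline and
  material, old/new responses) in which short-deadline responses are driven
  by familiarity alone (recollection forced to 0) and long-deadline
  responses by the full DPSD process mixture;

plus manual-volumetry tables (raw ROI volume and TIV per hemisphere) for
patients and a separate volumetric control sample, constructed so that
TIV-corrected control volumes Z-score to mean ≈ 0, SD ≈ 1 per ROI and each
patient's Z hits a configurable lesion profile.

Ground-truth brain–behavior structure is planted through per-(ROI, process)
slopes: a participant's true recollection probability and familiarity d'
are linear in their bilateral volume Z-scores, plus Gaussian
between-subject noise, with recollection clipped to [0, 0.999].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import substream

__all__ = [
    "DEFAULT_CRITERIA",
    "EffectSpec",
    "CohortSpec",
    "TrueParticipantParams",
    "Cohort",
    "study_like_profiles",
    "generate_cohort",
    "generate_volumes",
]

# Equally spaced criteria spanning the foil distribution: participants are
# instructed to use the full confidence scale.
DEFAULT_CRITERIA = (-1.2, -0.6, 0.0, 0.6, 1.2)

ROIS = ("HPC", "ERC", "PRC", "PHC", "amygdala", "temporal_pole")
HEMISPHERES = ("L", "R")

# Mean TIV-corrected volume ratio and relative SD per ROI (one hemisphere).
# Magnitudes follow typical adult morphometry: HPC ~3.2 cm^3, ERC ~0.65,
# PRC ~0.9, PHC ~0.8, amygdala ~1.5, temporal pole ~6 cm^3, TIV ~1.5 L.
ROI_MEAN_RATIO = {
    "HPC": 3200 / 1.5e6,
    "ERC": 650 / 1.5e6,
    "PRC": 900 / 1.5e6,
    "PHC": 800 / 1.5e6,
    "amygdala": 1500 / 1.5e6,
    "temporal_pole": 6000 / 1.5e6,
}
ROI_REL_SD = 0.10
TIV_MEAN, TIV_SD = 1.5e6, 1.2e5


def study_like_profiles() -> dict:
    """Per-patient (ROI, hemisphere) → target volume Z lesion profiles.

    Emulates a 9-patient cohort: one selective right-PRC lesion case
    (index 0), seven hippocampal cases with variable entorhinal involvement
    and subthreshold parahippocampal volume loss (indices 1–7), and one
    mixed hippocampal + right-PRC case (index 8).  No patient's PHC falls
    below the −1.67 lesion cutoff.
    """
    return {
        0: {("PRC", "R"): -3.0, ("PRC", "L"): 0.1, ("PHC", "L"): -1.6,
            ("PHC", "R"): -1.5, ("HPC", "L"): -0.2, ("HPC", "R"): -0.4,
            ("ERC", "L"): 0.3, ("ERC", "R"): -0.6},
        1: {("HPC", "L"): -2.4, ("HPC", "R"): -2.8, ("ERC", "L"): -1.9,
            ("ERC", "R"): -0.8, ("PHC", "L"): -0.9, ("PHC", "R"): -1.1},
        2: {("HPC", "L"): -1.9, ("HPC", "R"): -1.8, ("PHC", "L"): -0.4,
            ("PHC", "R"): -0.6},
        3: {("HPC", "L"): -3.2, ("HPC", "R"): -3.0, ("ERC", "L"): -2.1,
            ("ERC", "R"): -1.9, ("PHC", "L"): -1.5, ("PHC", "R"): -1.3},
        4: {("HPC", "L"): -2.0, ("HPC", "R"): -0.9, ("PHC", "L"): -0.7,
            ("PHC", "R"): -0.5},
        5: {("HPC", "L"): -2.8, ("HPC", "R"): -2.6, ("PHC", "L"): -1.2,
            ("PHC", "R"): -1.0},
        6: {("HPC", "L"): -1.8, ("HPC", "R"): -1.7, ("PHC", "L"): -0.3,
            ("PHC", "R"): -0.2},
        7: {("HPC", "L"): -2.2, ("HPC", "R"): -2.0, ("ERC", "L"): -1.8,
            ("ERC", "R"): -1.0, ("PHC", "L"): -1.0, ("PHC", "R"): -0.8},
        8: {("HPC", "L"): -2.6, ("HPC", "R"): -2.4, ("PRC", "L"): -0.5,
            ("PRC", "R"): -2.0, ("PHC", "L"): -1.1, ("PHC", "R"): -0.9,
            ("amygdala", "L"): -1.8},
    }


@dataclass
class EffectSpec:
    """Ground-truth brain–behavior structure.

    ``slopes`` maps (ROI, process) to the change in the true process value
    (probability scale for recollection, d' scale for familiarity) per unit
    bilateral volume Z.  ``lesion_profiles`` maps patient index to a
    per-(ROI, hemisphere) target Z map; patients without a profile get
    bilateral Z drawn from N(0, 0.75) truncated to [-3, +1] per ROI,
    independently across ROIs.
    """

    # Baseline recollection sits mid-scale so the linear volume->R map stays
    # inside [0, 1] across the lesion-profile range [-3, +1] at the default
    # slope (clipping only in the extreme tail); baseline familiarity d' is a
    # typical healthy-control discriminability.
    beta0_R: float = 0.40
    beta0_F: float = 1.2
    slopes: dict = field(default_factory=lambda: {
        ("HPC", "recollection"): 0.35,
        ("PHC", "familiarity"): 0.35,
    })
    lesion_profiles: dict | None = field(default_factory=study_like_profiles)

    def __post_init__(self):
        for (roi, process) in self.slopes:
            if roi not in ROIS:
                raise ValueError(f"unknown ROI {roi!r} in slopes")
            if process not in ("recollection", "familiarity"):
                raise ValueError(f"unknown process {process!r} in slopes")
        if self.lesion_profiles:
            for pidx, profile in self.lesion_profiles.items():
                for (roi, hemi) in profile:
                    if roi not in ROIS:
                        raise ValueError(f"unknown ROI {roi!r} in lesion profile {pidx}")


@dataclass
class CohortSpec:
    """Study design parameters for one synthetic cohort."""

    n_patients: int = 9
    n_controls_behavior: int = 14
    n_controls_volumetry: int = 48
    n_targets_roc: int = 80
    n_targets_rdp: int = 30  # per deadline condition
    materials: tuple = ("faces", "scenes")
    seed: int = 0
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    noise_sd_R: float = 0.08
    noise_sd_F: float = 0.15
    criteria: tuple = DEFAULT_CRITERIA
    # study-like missingness: behavioral controls without data per paradigm
    n_missing_roc_controls: int = 2
    n_missing_rdp_controls: int = 5

    def __post_init__(self):
        for name in ("n_patients", "n_controls_behavior", "n_controls_volumetry",
                     "n_targets_roc", "n_targets_rdp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.materials:
            raise ValueError("materials must be non-empty")
        if self.noise_sd_R < 0 or self.noise_sd_F < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_missing_roc_controls >= self.n_controls_behavior:
            raise ValueError("cannot mark all behavioral controls missing")
        if self.n_missing_rdp_controls >= self.n_controls_behavior:
            raise ValueError("cannot mark all behavioral controls missing")


@dataclass
class TrueParticipantParams:
    """Ground truth for one participant (recovery-test registry entry)."""

    participant: str
    group: str
    age: float
    true_R: dict            # "material|paradigm" -> recollection probability
    true_dprime: dict       # "material|paradigm" -> familiarity d'
    volume_z: dict          # (roi, hemisphere) -> target Z (patients/controls w/ MRI)
    tiv_mm3: float | None


@dataclass
class Cohort:
    """Generated trial tables, volumetry and ground-truth registry."""

    spec: CohortSpec
    roc_trials: pd.DataFrame
    rdp_trials: pd.DataFrame
    volumes: pd.DataFrame
    participants: pd.DataFrame
    truth: dict  # participant -> TrueParticipantParams

    def write(self, outdir):
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.roc_trials.to_csv(outdir / "roc_trials.csv", index=False)
        self.rdp_trials.to_csv(outdir / "rdp_trials.csv", index=False)
        self.volumes.to_csv(outdir / "volumes.csv", index=False)
        self.participants.to_csv(outdir / "participants.csv", index=False)
        truth = {}
        for pid, t in self.truth.items():
            d = asdict(t)
            d["volume_z"] = {f"{r}|{h}": z for (r, h), z in t.volume_z.items()}
            truth[pid] = d
        with open(outdir / "truth.json", "w") as fh:
            json.dump({"seed": self.spec.seed, "participants": truth}, fh, indent=2)


# ---------------------------------------------------------------------------
# generative model pieces


def dpsd_confidence_probs(R, dprime, criteria):
    """Category probabilities (1..6) for targets and foils under DPSD.

    Recollected targets respond with the highest confidence category.
    """
    c = np.asarray(criteria, float)
    edges_t = norm.cdf(dprime - c)       # P(strength > c_i) for familiarity
    edges_f = norm.cdf(-c)
    # cumulative "old-ward" probabilities at criteria 5..1
    cum_t = R + (1 - R) * edges_t[::-1]
    cum_f = edges_f[::-1]
    hc = np.concatenate([[0.0], cum_t, [1.0]])
    fc = np.concatenate([[0.0], cum_f, [1.0]])
    p_t = np.diff(hc)[::-1]
    p_f = np.diff(fc)[::-1]
    return np.clip(p_t, 0, 1), np.clip(p_f, 0, 1)


def _draw_profile(rng) -> dict:
    """Random patient lesion profile: independent bilateral volume Z per ROI.

    Truncated to [-3, +1]: a damage cohort spans intact to severely
    atrophic structures but not appreciably above the control mean.
    """
    profile = {}
    for roi in ROIS:
        z = float(np.clip(rng.normal(0.0, 0.75), -3.0, 1.0))
        for hemi in HEMISPHERES:
            profile[(roi, hemi)] = z + float(rng.normal(0.0, 0.1))
    return profile


def _complete_profile(profile: dict, rng) -> dict:
    """Fill unspecified (ROI, hemisphere) entries with small normal values."""
    full = {}
    for roi in ROIS:
        for hemi in HEMISPHERES:
            if (roi, hemi) in profile:
                full[(roi, hemi)] = float(profile[(roi, hemi)])
            else:
                full[(roi, hemi)] = float(rng.normal(0.0, 0.3))
    return full


def _bilateral(profile: dict, roi: str) -> float:
    return (profile[(roi, "L")] + profile[(roi, "R")]) / 2.0


def _true_processes(spec: CohortSpec, profile: dict | None, rng):
    """True (R, d') per condition from baselines, slopes and latent noise.

    Latent between-subject noise is drawn independently per
    (material, paradigm) cell, so the only participant-level structure
    shared across conditions is the volume-driven signal itself.
    Returned dicts are keyed by "material|paradigm".
    """
    es = spec.effect_spec
    true_R, true_F = {}, {}
    r0, f0 = es.beta0_R, es.beta0_F
    if profile is not None:
        for (roi, process), slope in es.slopes.items():
            shift = slope * _bilateral(profile, roi)
            if process == "recollection":
                r0 += shift
            else:
                f0 += shift
    for material in spec.materials:
        for paradigm in ("ROC", "RDP"):
            r = r0 + rng.normal(0.0, spec.noise_sd_R)
            f = f0 + rng.normal(0.0, spec.noise_sd_F)
            if r < 0.0 or r > 0.999:
                warnings.warn("true recollection clipped to [0, 0.999]",
                              stacklevel=3)
            true_R[f"{material}|{paradigm}"] = float(np.clip(r, 0.0, 0.999))
            true_F[f"{material}|{paradigm}"] = float(f)
    return true_R, true_F


# ---------------------------------------------------------------------------
# public generators


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate behavioral trials, volumetry and ground truth for a cohort.

    Deterministic given ``spec`` (including its seed): every stochastic
    draw flows from named, per-participant substreams of the one seed.
    """
    es = spec.effect_spec
    patient_ids = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    cb_ids = [f"CB{i + 1:02d}" for i in range(spec.n_controls_behavior)]
    cv_ids = [f"CV{i + 1:02d}" for i in range(spec.n_controls_volumetry)]

    truth: dict = {}
    profile_rng = substream(spec.seed, "profiles")
    profiles = {}
    for i, pid in enumerate(patient_ids):
        given = (es.lesion_profiles or {}).get(i)
        if given is not None:
            profiles[pid] = _complete_profile(given, profile_rng)
        else:
            profiles[pid] = _draw_profile(profile_rng)

    age_rng = substream(spec.seed, "ages")
    roc_rows, rdp_rows = [], []
    part_rows = []
    behavioral = [(pid, "patient") for pid in patient_ids] + \
                 [(pid, "control_behavior") for pid in cb_ids]

    missing_rng = substream(spec.seed, "missingness")
    missing_roc = set(missing_rng.choice(cb_ids, size=spec.n_missing_roc_controls,
                                         replace=False))
    missing_rdp = set(missing_rng.choice(cb_ids, size=spec.n_missing_rdp_controls,
                                         replace=False))

    c = np.asarray(spec.criteria, float)
    c_rdp = float(np.mean(c))  # single old/new criterion at the criteria midpoint

    for idx, (pid, group) in enumerate(behavioral):
        rng = substream(spec.seed, "behavior", idx)
        profile = profiles.get(pid)
        true_R, true_F = _true_processes(spec, profile, rng)
        age = float(np.clip(age_rng.normal(55 if group == "patient" else 62, 8), 20, 90))
        truth[pid] = TrueParticipantParams(
            participant=pid, group=group, age=age,
            true_R=true_R, true_dprime=true_F,
            volume_z=profiles.get(pid, {}), tiv_mm3=None,
        )
        part_rows.append({"participant": pid, "group": group, "age": age})

        for material in spec.materials:
            # --- confidence-rating paradigm
            R, d = true_R[f"{material}|ROC"], true_F[f"{material}|ROC"]
            if not (group == "control_behavior" and pid in missing_roc):
                p_t, p_f = dpsd_confidence_probs(R, d, c)
                t_counts = rng.multinomial(spec.n_targets_roc, p_t / p_t.sum())
                f_counts = rng.multinomial(spec.n_targets_roc, p_f / p_f.sum())
                for status, counts in (("target", t_counts), ("foil", f_counts)):
                    for cat in range(6):
                        roc_rows.extend(
                            {"participant": pid, "group": group,
                             "material": material, "item_status": status,
                             "confidence": cat + 1}
                            for _ in range(int(counts[cat])))
            # --- response-deadline paradigm
            R, d = true_R[f"{material}|RDP"], true_F[f"{material}|RDP"]
            if not (group == "control_behavior" and pid in missing_rdp):
                for deadline in ("short", "long"):
                    R_eff = 0.0 if deadline == "short" else R
                    p_old_t = R_eff + (1 - R_eff) * norm.cdf(d - c_rdp)
                    p_old_f = norm.cdf(-c_rdp)
                    hits = rng.binomial(spec.n_targets_rdp, p_old_t)
                    fas = rng.binomial(spec.n_targets_rdp, p_old_f)
                    for status, n_old, n_tot in (("target", hits, spec.n_targets_rdp),
                                                 ("foil", fas, spec.n_targets_rdp)):
                        rdp_rows.extend(
                            {"participant": pid, "group": group,
                             "material": material, "deadline": deadline,
                             "item_status": status, "response": "old"}
                            for _ in range(int(n_old)))
                        rdp_rows.extend(
                            {"participant": pid, "group": group,
                             "material": material, "deadline": deadline,
                             "item_status": status, "response": "new"}
                            for _ in range(int(n_tot - n_old)))

    for i, pid in enumerate(cv_ids):
        age = float(np.clip(age_rng.normal(62, 10), 20, 90))
        truth[pid] = TrueParticipantParams(
            participant=pid, group="control_volumetry", age=age,
            true_R={}, true_dprime={}, volume_z={}, tiv_mm3=None,
        )
        part_rows.append({"participant": pid, "group": "control_volumetry", "age": age})

    volumes = _generate_volume_table(spec, profiles, truth)

    return Cohort(
        spec=spec,
        roc_trials=pd.DataFrame(roc_rows),
        rdp_trials=pd.DataFrame(rdp_rows),
        volumes=volumes,
        participants=pd.DataFrame(part_rows),
        truth=truth,
    )


def _generate_volume_table(spec: CohortSpec, profiles: dict, truth: dict | None = None):
    """Raw volume + TIV rows for patients and volumetric controls.

    Control TIV-corrected ratios are drawn around ROI-specific means so
    that Z-scoring controls against their own norms gives mean ≈ 0,
    SD ≈ 1; patient ratios are shifted to hit the lesion profile's target Z
    in population norms.
    """
    rng = substream(spec.seed, "volumes")
    rows = []
    cv_ids = [f"CV{i + 1:02d}" for i in range(spec.n_controls_volumetry)]
    for pid in cv_ids:
        tiv = float(np.clip(rng.normal(TIV_MEAN, TIV_SD), 1.0e6, 2.2e6))
        if truth is not None and pid in truth:
            truth[pid].tiv_mm3 = tiv
        for roi in ROIS:
            m = ROI_MEAN_RATIO[roi]
            s = ROI_REL_SD * m
            for hemi in HEMISPHERES:
                ratio = max(rng.normal(m, s), 0.2 * m)
                rows.append({"participant": pid, "group": "control_volumetry",
                             "roi": roi, "hemisphere": hemi,
                             "volume_mm3": ratio * tiv, "tiv_mm3": tiv})
    for i in range(spec.n_patients):
        pid = f"P{i + 1:02d}"
        profile = profiles[pid]
        tiv = float(np.clip(rng.normal(TIV_MEAN, TIV_SD), 1.0e6, 2.2e6))
        if truth is not None and pid in truth:
            truth[pid].tiv_mm3 = tiv
        for roi in ROIS:
            m = ROI_MEAN_RATIO[roi]
            s = ROI_REL_SD * m
            for hemi in HEMISPHERES:
                ratio = max(m + profile[(roi, hemi)] * s, 0.05 * m)
                rows.append({"participant": pid, "group": "patient",
                             "roi": roi, "hemisphere": hemi,
                             "volume_mm3": ratio * tiv, "tiv_mm3": tiv})
    return pd.DataFrame(rows)


def generate_volumes(spec: CohortSpec) -> pd.DataFrame:
    """Standalone volumetry table (same draws as the full cohort)."""
    es = spec.effect_spec
    profile_rng = substream(spec.seed, "profiles")
    profiles = {}
    for i in range(spec.n_patients):
        pid = f"P{i + 1:02d}"
        given = (es.lesion_profiles or {}).get(i)
        if given is not None:
            profiles[pid] = _complete_profile(given, profile_rng)
        else:
            profiles[pid] = _draw_profile(profile_rng)
    return _generate_volume_table(spec, profiles)
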