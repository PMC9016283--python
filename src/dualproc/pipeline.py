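"""End-to-end orchestration: generate → estimate → normalize → infer.

A single seeded configuration drives the whole pipeline; every stage
output is written to the run directory together with a manifest recording
the package version, seed and a hash of the analysis-relevant
configuration, so that identical configs rerun to identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import child_seed
from .cohort import Cohort, CohortSpec, EffectSpec, generate_cohort
from .dpsd import dpsd_estimates
from .inference import (
    ImputationConfig,
    attach_volume,
    build_long_scores,
    impute_chained,
    mixed_anova_mi,
    zscore_behavior,
)
from .lmm import fit_volume_lmm, permutation_pvalues
from .rdp import rdp_estimates
from .volumetry import LESION_CUTOFF, classify_patient, zscore_table, ZScoredVolume

log = logging.getLogger("dualproc")

MODEL_ROIS = ("HPC", "PRC", "ERC", "PHC")


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serialisable)."""

    mode: str = "synthetic"          # or "csv"
    input_dir: str | None = None     # csv mode: directory with the trial tables
    outdir: str = "runs/default"
    seed: int = 0
    cohort: dict = field(default_factory=dict)   # CohortSpec overrides
    objective: str = "sse"
    restarts: int = 10
    correction: str = "loglinear"
    cutoff: float = LESION_CUTOFF
    m_imputations: int = 5
    imputation_method: str = "pmm"
    n_perm: int = 0                  # 0 disables permutation p-values
    include_age: bool = False
    hemispheres: str = "bilateral"   # "left" | "right" | "bilateral"

    def __post_init__(self):
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be 'synthetic' or 'csv'")
        if self.mode == "csv" and not self.input_dir:
            raise ValueError("csv mode requires input_dir")
        if self.hemispheres not in ("left", "right", "bilateral"):
            raise ValueError("hemispheres must be left, right or bilateral")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location is not analysis-relevant
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _cohort_spec(config: RunConfig) -> CohortSpec:
    kwargs = dict(config.cohort)
    effect = kwargs.pop("effect_spec", None)
    if isinstance(effect, dict):
        effect = EffectSpec(**effect)
    if effect is not None:
        kwargs["effect_spec"] = effect
    kwargs.setdefault("seed", child_seed(config.seed, "cohort"))
    return CohortSpec(**kwargs)


def _load_csv_inputs(input_dir):
    d = Path(input_dir)
    roc = pd.read_csv(d / "roc_trials.csv")
    rdp = pd.read_csv(d / "rdp_trials.csv")
    volumes = pd.read_csv(d / "volumes.csv")
    ppath = d / "participants.csv"
    participants = pd.read_csv(ppath) if ppath.exists() else None
    return roc, rdp, volumes, participants


def true_rdp_processes(R: float, dprime: float, criterion: float = 0.0):
    """Closed-form generative values recovered by the deadline subtraction.

    The short deadline isolates familiarity so short d' = d'; the long
    deadline mixes in recollection, giving a d' of
    z(R + (1−R)Φ(d'−c)) + c, hence a long-minus-short gap of
    z(R + (1−R)Φ(d'−c)) + c − d'.
    """
    p_long = R + (1 - R) * norm.cdf(dprime - criterion)
    long_d = norm.ppf(p_long) + criterion
    return dprime, float(long_d - dprime)


def recovery_report(truth: dict, dpsd_est: pd.DataFrame,
                    rdp_est: pd.DataFrame) -> pd.DataFrame:
    """Bias/RMSE of process estimates against the generative registry.

    Also recovers each planted (ROI, process) slope by OLS of the process
    estimates on the ground-truth bilateral volume Z across patients.
    """
    rows = []
    err_roc_R, err_roc_F, err_rdp_R, err_rdp_F = [], [], [], []
    for rec in dpsd_est.itertuples(index=False):
        t = truth.get(rec.participant)
        key = f"{rec.material}|ROC"
        if t is None or key not in t.true_R:
            continue
        err_roc_R.append(rec.R - t.true_R[key])
        err_roc_F.append(rec.dprime - t.true_dprime[key])
    for rec in rdp_est.itertuples(index=False):
        t = truth.get(rec.participant)
        key = f"{rec.material}|RDP"
        if t is None or key not in t.true_R:
            continue
        fam, recoll = true_rdp_processes(t.true_R[key], t.true_dprime[key])
        err_rdp_F.append(rec.familiarity - fam)
        err_rdp_R.append(rec.recollection - recoll)
    for name, errs in (("ROC_R", err_roc_R), ("ROC_dprime", err_roc_F),
                       ("RDP_familiarity", err_rdp_F),
                       ("RDP_recollection", err_rdp_R)):
        e = np.asarray(errs, float)
        rows.append({"parameter": name, "n": len(e),
                     "bias": float(e.mean()) if len(e) else np.nan,
                     "rmse": float(np.sqrt((e ** 2).mean())) if len(e) else np.nan})
    # planted slope recovery across patients
    patients = {pid: t for pid, t in truth.items() if t.group == "patient"}
    est_by = {"recollection": {}, "familiarity": {}}
    for rec in dpsd_est.itertuples(index=False):
        if rec.participant in patients:
            est_by["recollection"].setdefault(rec.participant, []).append(rec.R)
            est_by["familiarity"].setdefault(rec.participant, []).append(rec.dprime)
    for roi in ("HPC", "PHC", "PRC", "ERC"):
        for process in ("recollection", "familiarity"):
            xs, ys = [], []
            for pid, t in patients.items():
                if not t.volume_z or pid not in est_by[process]:
                    continue
                zL = t.volume_z.get((roi, "L"))
                zR = t.volume_z.get((roi, "R"))
                if zL is None or zR is None:
                    continue
                xs.append((zL + zR) / 2.0)
                ys.append(np.mean(est_by[process][pid]))
            if len(xs) >= 3 and np.std(xs) > 0:
                slope = float(np.polyfit(xs, ys, 1)[0])
                rows.append({"parameter": f"slope_{roi}_{process}", "n": len(xs),
                             "bias": slope, "rmse": np.nan})
    return pd.DataFrame(rows)


def _categorical_analyses(long_z, classification, m, method, seed):
    """Table-1-style ANOVAs for the lesion-defined patient groupings.

    Three comparisons when the cohort supports them: PRC-lesion case(s)
    vs. controls, HPC-lesion cases vs. controls (both on imputed raw
    scores), and PRC vs. HPC cases on control-referenced Z-scores.
    """
    prc = [p for p, c in classification.items() if c == "PRC-lesioned/HPC-intact"]
    hpc = [p for p, c in classification.items() if c == "HPC-lesioned/PRC-intact"]
    controls = sorted(long_z.loc[long_z["group"] == "control_behavior",
                                 "participant"].unique())
    out = []

    def run(sub, label, dv):
        wide = sub.pivot_table(index="participant", columns=["process", "material",
                                                             "paradigm"],
                               values=dv, aggfunc="first", dropna=False)
        groups = sub.groupby("participant")["grp2"].first()
        cells = list(wide.columns)
        flat = wide.copy()
        flat.columns = [f"c{k}" for k in range(len(cells))]  # patsy-safe names
        cfg = ImputationConfig(m=m, method=method, seed=seed)
        imputed = impute_chained(flat.reset_index(drop=True), cfg) \
            if flat.isna().any().any() else [flat.reset_index(drop=True)] * m
        tables = []
        for imp in imputed:
            imp = imp.copy()
            imp.index = wide.index
            imp.columns = pd.MultiIndex.from_tuples(cells)
            t = imp.stack(list(range(3)), future_stack=True) \
                .rename("score").reset_index()
            t.columns = ["participant", "process", "material", "paradigm", "score"]
            t["group"] = t["participant"].map(groups)
            tables.append(t)
        res = mixed_anova_mi(tables)
        res.insert(0, "analysis", label)
        return res

    if prc and controls:
        sub = long_z[long_z["participant"].isin(prc + controls)].copy()
        sub["grp2"] = np.where(sub["participant"].isin(prc), "PRC", "CTR")
        out.append(run(sub, "PRC vs CTR", "score"))
    if hpc and controls:
        sub = long_z[long_z["participant"].isin(hpc + controls)].copy()
        sub["grp2"] = np.where(sub["participant"].isin(hpc), "HPC", "CTR")
        out.append(run(sub, "HPC vs CTR", "score"))
    if prc and hpc:
        sub = long_z[long_z["participant"].isin(prc + hpc)].copy()
        sub["grp2"] = np.where(sub["participant"].isin(prc), "PRC", "HPC")
        out.append(run(sub, "PRC vs HPC (z)", "score_z"))
    if not out:
        return pd.DataFrame(columns=["analysis", "effect", "df1", "df2",
                                     "F_min", "F_max", "p_min", "p_max"])
    return pd.concat(out, ignore_index=True)


def _continuous_analyses(long_z, zvols, participants, config: RunConfig):
    """Table-2-style mixed models per ROI, plus per-process follow-ups."""
    hemi = {"left": "L", "right": "R", "bilateral": "bilateral"}[config.hemispheres]
    patients = long_z[long_z["group"] == "patient"]
    rows, follow_rows, perm_rows = [], [], []
    for roi in MODEL_ROIS:
        table = attach_volume(patients, zvols, roi, hemisphere=hemi,
                              participants=participants)
        try:
            res = fit_volume_lmm(table, include_age=config.include_age,
                                 seed=child_seed(config.seed, "lmm"))
        except ValueError as exc:
            log.warning("ROI %s model inestimable: %s", roi, exc)
            rows.append({"roi": roi, "effect": "Volume", "df1": np.nan,
                         "df2": np.nan, "F": np.nan, "p": np.nan,
                         "flag": f"error: {exc}"})
            continue
        anova = res.anova()
        anova = anova[anova["effect"].str.contains("Volume")]
        for r in anova.itertuples(index=False):
            rows.append({"roi": roi, "effect": r.effect, "df1": r.df1,
                         "df2": r.df2, "F": r.F, "p": r.p,
                         "flag": "singular-refit" if res.fallback_from else ""})
        for process in ("recollection", "familiarity"):
            sub = table[table["process"] == process]
            try:
                fres = fit_volume_lmm(sub, include_age=config.include_age,
                                      seed=child_seed(config.seed, "lmm-follow"))
                fan = fres.anova(effects=["Volume"]).iloc[0]
                follow_rows.append({"roi": roi, "process": process,
                                    "df1": fan["df1"], "df2": fan["df2"],
                                    "F": fan["F"], "p": fan["p"]})
            except ValueError as exc:
                follow_rows.append({"roi": roi, "process": process,
                                    "df1": np.nan, "df2": np.nan,
                                    "F": np.nan, "p": np.nan,
                                    "flag": f"error: {exc}"})
        if config.n_perm:
            perm = permutation_pvalues(res, n_perm=config.n_perm,
                                       seed=child_seed(config.seed, "perm"))
            perm = perm[perm["effect"].str.contains("Volume")]
            perm.insert(0, "roi", roi)
            perm_rows.append(perm)
    table2 = pd.DataFrame(rows)
    follow = pd.DataFrame(follow_rows)
    perms = pd.concat(perm_rows, ignore_index=True) if perm_rows else None
    return table2, follow, perms


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return a results bundle and write all outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    truth = None
    if config.mode == "synthetic":
        spec = _cohort_spec(config)
        log.info("generating synthetic cohort (seed=%s)", spec.seed)
        cohort = generate_cohort(spec)
        cohort.write(outdir)
        roc, rdp, volumes = cohort.roc_trials, cohort.rdp_trials, cohort.volumes
        participants = cohort.participants
        truth = cohort.truth
    else:
        log.info("loading CSV inputs from %s", config.input_dir)
        roc, rdp, volumes, participants = _load_csv_inputs(config.input_dir)

    log.info("stage 1a: DPSD fits (objective=%s)", config.objective)
    dpsd_est = dpsd_estimates(roc, objective=config.objective,
                              restarts=config.restarts,
                              seed=child_seed(config.seed, "dpsd"))
    dpsd_est.to_csv(outdir / "dpsd_estimates.csv", index=False)

    log.info("stage 1b: RDP estimates (correction=%s)", config.correction)
    rdp_est = rdp_estimates(rdp, correction=config.correction)
    rdp_est.to_csv(outdir / "rdp_estimates.csv", index=False)

    log.info("stage 2: volumetry Z-scoring")
    zvols = zscore_table(volumes, cutoff=config.cutoff)
    zvols.to_csv(outdir / "volume_zscores.csv", index=False)
    classification = {}
    for pid, sub in zvols[zvols["group"] == "patient"].groupby("participant"):
        entries = [ZScoredVolume(r.participant, r.roi, r.hemisphere, r.z, r.lesioned)
                   for r in sub.itertuples(index=False)
                   if r.hemisphere in ("L", "R")]
        classification[pid] = classify_patient(entries, cutoff=config.cutoff)
    with open(outdir / "lesion_classification.json", "w") as fh:
        json.dump(classification, fh, indent=2)

    log.info("stage 3: inference")
    long = build_long_scores(dpsd_est, rdp_est)
    has_controls = (long["group"] == "control_behavior").any()
    if has_controls:
        long_z = zscore_behavior(long)
        table1 = _categorical_analyses(long_z, classification,
                                       config.m_imputations,
                                       config.imputation_method,
                                       child_seed(config.seed, "imputation"))
        table1.to_csv(outdir / "table1_categorical.csv", index=False)
    else:
        long_z = long.copy()
        long_z["score_z"] = long_z["score"]
        table1 = None
    table2, follow, perms = _continuous_analyses(long_z, zvols, participants, config)
    table2.to_csv(outdir / "table2_continuous.csv", index=False)
    follow.to_csv(outdir / "table2_followups.csv", index=False)
    if perms is not None:
        perms.to_csv(outdir / "table2_permutation.csv", index=False)

    recovery = None
    if truth is not None:
        recovery = recovery_report(truth, dpsd_est, rdp_est)
        recovery.to_csv(outdir / "recovery_report.csv", index=False)

    manifest = {
        "package": "dualproc",
        "version": _pkg_version(),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("run complete: %s", outdir)
    return {
        "dpsd_estimates": dpsd_est, "rdp_estimates": rdp_est,
        "volume_zscores": zvols, "classification": classification,
        "table1": table1, "table2": table2, "table2_followups": follow,
        "permutation": perms, "recovery": recovery, "manifest": manifest,
    }


def _pkg_version() -> str:
    from dualproc import __version__
    return __version__
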