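"""Normative ROI volumetry: TIV correction, control Z-scoring, lesion calls.

Raw ROI volumes are divided by total intracranial volume (TIV), expressed
as Z-scores against the mean and (unbiased, n−1) SD of the TIV-corrected
volumes of a control sample, and classified as lesioned when Z falls
strictly below a conventional cutoff of −1.67 (the 5th percentile of a
normal control distribution).  Bilateral summaries average the left and
right hemisphere Z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

__all__ = [
    "ROIS",
    "LESION_CUTOFF",
    "ROIVolumeRecord",
    "NormativeReference",
    "ZScoredVolume",
    "tiv_correct",
    "zscore_volume",
    "bilateral_average",
    "classify_patient",
    "build_norms",
    "zscore_table",
]

ROIS = ("HPC", "ERC", "PRC", "PHC", "amygdala", "temporal_pole")
HEMISPHERES = ("L", "R")
LESION_CUTOFF = -1.67


@dataclass(frozen=True)
class ROIVolumeRecord:
    participant: str
    roi: str
    hemisphere: str
    volume_mm3: float
    tiv_mm3: float

    def __post_init__(self):
        if self.roi not in ROIS:
            raise ValueError(f"unknown ROI {self.roi!r}; expected one of {ROIS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError("hemisphere must be 'L' or 'R'")
        if self.tiv_mm3 <= 0:
            raise ValueError("TIV must be positive")
        if self.volume_mm3 <= 0:
            raise ValueError("volume must be positive")
        if self.volume_mm3 >= self.tiv_mm3:
            raise ValueError("ROI volume must be smaller than TIV")


def tiv_correct(record: ROIVolumeRecord) -> float:
    """Dimensionless corrected volume: raw volume divided by TIV."""
    return record.volume_mm3 / record.tiv_mm3


@dataclass(frozen=True)
class ZScoredVolume:
    participant: str
    roi: str
    hemisphere: str  # "L", "R" or "bilateral"
    z: float
    lesioned: bool


class NormativeReference:
    """Per-(ROI, hemisphere) control norms of TIV-corrected volume."""

    def __init__(self, table: dict):
        # table: {(roi, hemi): {"mean": m, "sd": s, "n": n}}
        for key, v in table.items():
            if v["sd"] <= 0:
                raise ValueError(f"norm SD must be positive for {key}")
            if v["n"] < 2:
                raise ValueError(f"norms need at least 2 controls for {key}")
        self._table = dict(table)

    def __contains__(self, key):
        return key in self._table

    def __getitem__(self, key):
        return self._table[key]

    def to_json(self, path):
        serialisable = {f"{roi}|{hemi}": v for (roi, hemi), v in self._table.items()}
        with open(path, "w") as fh:
            json.dump(serialisable, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            raw = json.load(fh)
        return cls({tuple(k.split("|")): v for k, v in raw.items()})


def build_norms(volumes: pd.DataFrame, control_group: str = "control_volumetry") -> NormativeReference:
    """Estimate norms from a tidy volume table's control rows.

    Expects columns participant, group, roi, hemisphere, volume_mm3,
    tiv_mm3.  The SD is the unbiased (n−1) estimate.
    """
    ctr = volumes[volumes["group"] == control_group]
    if ctr.empty:
        raise ValueError(f"no rows with group == {control_group!r}")
    table = {}
    corrected = ctr["volume_mm3"] / ctr["tiv_mm3"]
    for (roi, hemi), idx in ctr.groupby(["roi", "hemisphere"]).groups.items():
        vals = corrected.loc[idx]
        table[(roi, hemi)] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n": int(len(vals)),
        }
    return NormativeReference(table)


def zscore_volume(record: ROIVolumeRecord, ref: NormativeReference,
                  cutoff: float = LESION_CUTOFF) -> ZScoredVolume:
    """Z-score one TIV-corrected volume against the control norms."""
    key = (record.roi, record.hemisphere)
    if key not in ref:
        raise KeyError(f"no normative entry for {key}")
    norm = ref[key]
    z = (tiv_correct(record) - norm["mean"]) / norm["sd"]
    return ZScoredVolume(record.participant, record.roi, record.hemisphere,
                         float(z), bool(z < cutoff))


def bilateral_average(left: ZScoredVolume, right: ZScoredVolume,
                      cutoff: float = LESION_CUTOFF) -> ZScoredVolume:
    """Average left and right hemisphere Z-scores for one ROI."""
    if left.participant != right.participant or left.roi != right.roi:
        raise ValueError("bilateral average requires the same participant and ROI")
    z = (left.z + right.z) / 2.0
    return ZScoredVolume(left.participant, left.roi, "bilateral", float(z),
                         bool(z < cutoff))


def classify_patient(zvols, cutoff: float = LESION_CUTOFF) -> str:
    """Categorical lesion label from per-hemisphere Z-scores.

    A structure counts as lesioned when either hemisphere falls strictly
    below the cutoff.  Returns one of ``PRC-lesioned/HPC-intact``,
    ``HPC-lesioned/PRC-intact``, ``mixed`` or ``none``.
    """
    by_key = {(v.roi, v.hemisphere): v for v in zvols}
    for roi in ("HPC", "PRC"):
        for hemi in HEMISPHERES:
            if (roi, hemi) not in by_key:
                raise ValueError(f"missing {roi} {hemi} entry")
    hpc = any(by_key[("HPC", h)].z < cutoff for h in HEMISPHERES)
    prc = any(by_key[("PRC", h)].z < cutoff for h in HEMISPHERES)
    if hpc and prc:
        return "mixed"
    if hpc:
        return "HPC-lesioned/PRC-intact"
    if prc:
        return "PRC-lesioned/HPC-intact"
    return "none"


def zscore_table(volumes: pd.DataFrame, ref: NormativeReference | None = None,
                 cutoff: float = LESION_CUTOFF,
                 control_group: str = "control_volumetry") -> pd.DataFrame:
    """Z-score every row of a tidy volume table; append bilateral rows.

    If ``ref`` is None, norms are built from the table's own control rows.
    """
    if ref is None:
        ref = build_norms(volumes, control_group=control_group)
    rows = []
    for rec in volumes.itertuples(index=False):
        record = ROIVolumeRecord(rec.participant, rec.roi, rec.hemisphere,
                                 rec.volume_mm3, rec.tiv_mm3)
        zv = zscore_volume(record, ref, cutoff)
        rows.append({"participant": rec.participant, "group": rec.group,
                     "roi": rec.roi, "hemisphere": rec.hemisphere,
                     "z": zv.z, "lesioned": zv.lesioned})
    out = pd.DataFrame(rows)
    bilat = (out.groupby(["participant", "group", "roi"], sort=False)["z"]
             .mean().reset_index())
    bilat["hemisphere"] = "bilateral"
    bilat["lesioned"] = bilat["z"] < cutoff
    return pd.concat([out, bilat[out.columns]], ignore_index=True)
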