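"""Standard-format I/O: covariate CSV, NIfTI volumes, score TSV, JSON.

Numeric round-trips are lossless at float64 (volumes float32; masks uint8).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import COVARIATE_MEANS, LiverVolume
from .zscore import SubjectScore, ZScoreMap

__all__ = [
    "write_covariates", "read_covariates",
    "write_volume", "read_volume", "write_zscore_map",
    "write_scores", "read_scores",
    "write_json", "read_json", "sha256_of",
]

SCORE_COLUMNS = ["subject_id", "suv_mean", "suv_sd", "suv_max", "z_max", "label"]


def write_covariates(path, covariates: pd.DataFrame,
                     labels: pd.Series | None = None) -> None:
    out = covariates.copy()
    if labels is not None:
        out["label"] = labels
    out.to_csv(path, index=True, float_format="%.17g")


def read_covariates(path) -> tuple[pd.DataFrame, pd.Series | None]:
    df = pd.read_csv(path, index_col=0)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label")
        bad = set(labels.unique()) - {"normal", "abnormal"}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
    unknown = [c for c in df.columns
               if c not in COVARIATE_MEANS and not c.startswith("suv_")]
    if unknown:
        raise ValueError("unknown covariate column(s): " + ", ".join(unknown))
    if df.isna().any().any():
        raise ValueError("missing values in covariate table")
    return df, labels


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def write_volume(suv_path, volume: LiverVolume, mask_path=None) -> None:
    aff = _affine(volume.voxel_size_mm)
    nib.save(nib.Nifti1Image(volume.suv.astype(np.float32), aff), str(suv_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(volume.mask.astype(np.uint8), aff),
                 str(mask_path))


def read_volume(suv_path, mask_path, subject_id: str = "") -> LiverVolume:
    img = nib.load(str(suv_path))
    msk = nib.load(str(mask_path))
    suv = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj)
    if suv.shape != mask.shape:
        raise ValueError(
            f"volume shape {suv.shape} != mask shape {mask.shape}")
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LiverVolume(suv=suv, mask=mask, voxel_size_mm=voxel,
                       subject_id=subject_id)


def write_zscore_map(path, zmap: ZScoreMap, voxel_size_mm) -> None:
    nib.save(nib.Nifti1Image(zmap.z.astype(np.float32),
                             _affine(voxel_size_mm)), str(path))


def write_scores(path, scores: list[SubjectScore]) -> None:
    pd.DataFrame([s.as_dict() for s in scores],
                 columns=SCORE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError("score table lacks column(s): " + ", ".join(missing))
    return df


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
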