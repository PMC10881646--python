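"""Per-voxel liver Z-score maps and per-subject summary scores.

Given a subject's liver-masked SUV volume and their covariate-estimated
background SUV mean E(Y) and SD(Y), each in-mask voxel y_i maps to

    Z_i = (y_i - E(Y)) / SD(Y)

so the map expresses deviation from the subject's own expected background in
SD units. Voxels outside the mask are NaN (undefined), so no downstream
maximum can leak from outside the liver. Per-subject anomaly scores are the
in-mask maxima SUV_max and Z_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import LiverVolume

__all__ = ["ZScoreMap", "SubjectScore", "observed_liver_stats",
           "compute_zscore_map", "score_subject", "SD_FLOOR"]

#: Smallest admissible estimated SD (SUV units); below this the normalization
#: is degenerate and refused.
SD_FLOOR = 1e-6


@dataclass
class ZScoreMap:
    """Z-score volume (NaN outside the mask) plus the E(Y), SD(Y) used."""

    z: np.ndarray
    mask: np.ndarray
    e_y: float
    sd_y: float
    subject_id: str = ""

    @property
    def z_max(self) -> float:
        return float(self.z[self.mask].max())


@dataclass
class SubjectScore:
    """Observed in-mask SUV statistics and the two anomaly scores."""

    subject_id: str
    suv_mean: float
    suv_sd: float
    suv_max: float
    z_max: float
    label: str

    def as_dict(self) -> dict:
        return {"subject_id": self.subject_id, "suv_mean": self.suv_mean,
                "suv_sd": self.suv_sd, "suv_max": self.suv_max,
                "z_max": self.z_max, "label": self.label}


def observed_liver_stats(volume: LiverVolume) -> tuple[float, float, float]:
    """In-mask (mean, SD, max) of the SUV; SD uses divisor n (population)."""
    vals = volume.suv[volume.mask]
    if vals.size == 0:
        raise ValueError("empty liver mask")
    return float(vals.mean()), float(vals.std()), float(vals.max())


def compute_zscore_map(volume: LiverVolume, e_y: float, sd_y: float
                       ) -> ZScoreMap:
    """Per-voxel (SUV - E(Y)) / SD(Y) inside the mask, NaN outside."""
    if not np.isfinite(e_y) or not np.isfinite(sd_y):
        raise ValueError("e_y and sd_y must be finite")
    if sd_y <= SD_FLOOR:
        raise ValueError(
            f"estimated SD {sd_y:g} at or below floor {SD_FLOOR:g}: "
            "degenerate normalization")
    z = np.full(volume.suv.shape, np.nan)
    z[volume.mask] = (volume.suv[volume.mask] - e_y) / sd_y
    return ZScoreMap(z=z, mask=volume.mask, e_y=float(e_y), sd_y=float(sd_y),
                     subject_id=volume.subject_id)


def score_subject(volume: LiverVolume, e_y: float, sd_y: float,
                  label: str = "normal") -> SubjectScore:
    """Summarize one subject: observed stats, SUV_max and Z_max.

    Z_max is taken from the Z-map maximum and cross-checked against the
    algebraic identity (SUV_max - E(Y)) / SD(Y).
    """
    suv_mean, suv_sd, suv_max = observed_liver_stats(volume)
    zmap = compute_zscore_map(volume, e_y, sd_y)
    z_max = zmap.z_max
    ident = (suv_max - e_y) / sd_y
    if abs(z_max - ident) > 1e-10:
        raise AssertionError(
            f"z_max {z_max!r} disagrees with (suv_max - e_y)/sd_y {ident!r}")
    return SubjectScore(subject_id=volume.subject_id, suv_mean=suv_mean,
                        suv_sd=suv_sd, suv_max=suv_max, z_max=z_max,
                        label=label)
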