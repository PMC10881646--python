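"""Synthetic cohorts and liver phantoms for the SUV-normalization analysis.

The generator emulates a whole-body FDG-PET screening cohort: per-subject
demographic and blood-chemistry covariates with realistic marginal moments, a
sparse linear link from covariates to each subject's background liver SUV mean
and SD, and 3-D liver phantoms (ellipsoidal mask, i.i.d. Gaussian voxel noise
at PET voxel geometry) with optional focal hot lesions in abnormal subjects.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATE_MEANS",
    "COVARIATE_SDS",
    "DEFAULT_MEAN_COEFFICIENTS",
    "CohortConfig",
    "LesionSpec",
    "LiverVolume",
    "generate_cohort",
    "generate_liver_volume",
]

#: Marginal mean of each covariate in the screening cohort (units as drawn from
#: a routine panel: cm, kg, kg/m^2, IU/L, mg/dL, g/dL, 1e4/uL, %, ...).
COVARIATE_MEANS: dict[str, float] = {
    "sex": 0.5,  # 0 = female, 1 = male
    "age": 55.73,
    "height": 164.74,
    "weight": 65.18,
    "bmi": 23.85,
    "brinkman_index": 325.84,
    "amylase": 73.92,
    "hdl_cholesterol": 61.69,
    "ldl_cholesterol": 124.5,
    "total_cholesterol": 202.76,
    "total_bilirubin": 0.9,
    "total_protein": 6.89,
    "platelet": 23.23,
    "albumin": 4.14,
    "cholinesterase": 334.02,
    "alkaline_phosphatase": 190.44,
    "triglyceride": 120.89,
    "alt": 24.61,
    "ast": 22.8,
    "gamma_gtp": 47.46,
    "insulin": 5.71,
    "hba1c": 5.8,
    "blood_glucose": 96.68,
    "creatinine": 0.76,
}

#: Marginal SD of each covariate (sex is Bernoulli(0.5), SD 0.5).
COVARIATE_SDS: dict[str, float] = {
    "sex": 0.5,
    "age": 10.63,
    "height": 8.95,
    "weight": 13.14,
    "bmi": 3.57,
    "brinkman_index": 448.03,
    "amylase": 32.36,
    "hdl_cholesterol": 17.15,
    "ldl_cholesterol": 31.7,
    "total_cholesterol": 34.34,
    "total_bilirubin": 0.33,
    "total_protein": 0.39,
    "platelet": 5.53,
    "albumin": 0.26,
    "cholinesterase": 69.26,
    "alkaline_phosphatase": 64.68,
    "triglyceride": 93.03,
    "alt": 21.88,
    "ast": 13.3,
    "gamma_gtp": 61.05,
    "insulin": 6.27,
    "hba1c": 0.79,
    "blood_glucose": 18.14,
    "creatinine": 0.27,
}

#: True sparse link from covariates to the background liver SUV mean (per-unit
#: slopes on the original covariate scale). The insulin slope is -0.003: the
#: published per-unit value (-3.202) would drive the SUV negative at the
#: cohort-mean insulin and is treated as a typographic/scale error.
DEFAULT_MEAN_COEFFICIENTS: dict[str, float] = {
    "sex": 0.05,
    "weight": 0.0033,
    "bmi": 0.02,
    "blood_glucose": 0.00006,
    "triglyceride": 0.0001,
    "total_cholesterol": 0.0002,
    "gamma_gtp": 0.00002,
    "total_protein": 0.037,
    "creatinine": 0.017,
    "insulin": -0.003,
    "albumin": 0.025,
    "cholinesterase": 0.00004,
}

DEFAULT_MEAN_INTERCEPT = 0.82
DEFAULT_SD_INTERCEPT = 0.228
DEFAULT_SD_WEIGHT_SLOPE = 0.0029

# Correlation between generated height and weight. BMI is computed exactly as
# weight/(height/100)^2; with independent height and weight its SD would be
# ~5.5 kg/m^2, far from the cohort's 3.57. rho = 0.71 reproduces BMI
# mean 23.86, SD 3.58 while keeping the arithmetic identity.
HEIGHT_WEIGHT_CORR = 0.71

#: Floor applied to each subject's latent SUV mean and SD (SUV units).
SUV_FLOOR = 0.05

DEFAULT_VOXEL_SIZE_MM = (5.47, 5.47, 3.25)
DEFAULT_GRID_SHAPE = (96, 96, 96)
DEFAULT_LIVER_SEMI_AXES_MM = (60.0, 45.0, 40.0)


@dataclass
class CohortConfig:
    """Parameters of the synthetic screening cohort.

    ``true_mean_coefficients`` / ``true_mean_intercept`` define the sparse
    linear link covariates -> background liver SUV mean; the SUV SD depends on
    weight only (``true_sd_intercept + true_sd_weight_slope * weight``). Both
    latent values receive Gaussian subject-level noise (``residual_sd_*``) and
    are floored at a small positive constant.
    """

    n_subjects: int = 7757
    abnormal_fraction: float = 13 / 7757
    covariate_means: Mapping[str, float] = field(
        default_factory=lambda: dict(COVARIATE_MEANS))
    covariate_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(COVARIATE_SDS))
    true_mean_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_COEFFICIENTS))
    true_mean_intercept: float = DEFAULT_MEAN_INTERCEPT
    true_sd_intercept: float = DEFAULT_SD_INTERCEPT
    true_sd_weight_slope: float = DEFAULT_SD_WEIGHT_SLOPE
    residual_sd_mean: float = 0.1
    residual_sd_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError(f"n_subjects must be >= 0, got {self.n_subjects}")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError(
                f"abnormal_fraction must be in [0, 1], got {self.abnormal_fraction}")
        for name, sd in self.covariate_sds.items():
            if sd <= 0:
                raise ValueError(f"covariate SD for {name!r} must be > 0, got {sd}")
        if self.residual_sd_mean < 0 or self.residual_sd_sd < 0:
            raise ValueError("residual SDs must be >= 0")
        # the SD link must stay positive over a plausible weight range
        w = self.covariate_means.get("weight", COVARIATE_MEANS["weight"])
        ws = self.covariate_sds.get("weight", COVARIATE_SDS["weight"])
        for wx in (w - 4 * ws, w + 4 * ws):
            if self.true_sd_intercept + self.true_sd_weight_slope * wx <= 0:
                raise ValueError(
                    "SD link non-positive at plausible weight "
                    f"{wx:.1f} kg; adjust intercept/slope")

    def replace(self, **kwargs) -> "CohortConfig":
        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            if not hasattr(new, k):
                raise AttributeError(k)
            setattr(new, k, v)
        return new


@dataclass
class LesionSpec:
    """Focal hot lesions inserted into abnormal subjects' livers.

    Spheres of ``radius_mm`` whose voxels get an additive SUV ``contrast``
    above the local background, placed uniformly among voxels at least
    ``radius_mm + placement_margin_mm`` inside the mask boundary.
    """

    n_lesions: int = 1
    radius_mm: float = 10.0
    contrast: float = 1.0
    placement_margin_mm: float = 3.0

    def validate(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.contrast <= 0:
            raise ValueError("contrast must be > 0 (focal positive alteration)")
        if self.placement_margin_mm < 0:
            raise ValueError("placement_margin_mm must be >= 0")


@dataclass
class LiverVolume:
    """A liver-masked SUV volume: 3-D SUV array, binary mask, voxel geometry."""

    suv: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.suv = np.asarray(self.suv, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.suv.shape != self.mask.shape:
            raise ValueError(
                f"suv shape {self.suv.shape} != mask shape {self.mask.shape}")
        if self.mask.dtype != bool:
            uniq = np.unique(self.mask)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask must be binary (0/1)")
            self.mask = self.mask.astype(bool)
        if not self.mask.any():
            raise ValueError("mask is empty")
        if np.isnan(self.suv[self.mask]).any():
            raise ValueError("NaN SUV inside mask")
        if (self.suv[self.mask] < 0).any():
            raise ValueError("negative SUV inside mask")

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())


def _draw_covariates(config: CohortConfig, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Draw the covariate table.

    sex ~ Bernoulli(mean); height/weight bivariate Gaussian with correlation
    HEIGHT_WEIGHT_CORR; bmi = weight/(height/100)^2 exactly; every other
    covariate an independent Gaussian at its configured mean/SD.
    """
    means, sds = config.covariate_means, config.covariate_sds
    cols: dict[str, np.ndarray] = {}
    cols["sex"] = (rng.random(n) < means.get("sex", 0.5)).astype(float)
    z_h = rng.standard_normal(n)
    z_w = rng.standard_normal(n)
    rho = HEIGHT_WEIGHT_CORR
    cols["height"] = means["height"] + sds["height"] * z_h
    cols["weight"] = means["weight"] + sds["weight"] * (
        rho * z_h + np.sqrt(1 - rho**2) * z_w)
    cols["bmi"] = cols["weight"] / (cols["height"] / 100.0) ** 2
    for name in means:
        if name in cols:
            continue
        cols[name] = means[name] + sds[name] * rng.standard_normal(n)
    # keep canonical column order
    order = [c for c in COVARIATE_MEANS if c in cols]
    order += [c for c in cols if c not in order]
    return pd.DataFrame({c: cols[c] for c in order})


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate covariates, latent SUV targets and normal/abnormal labels.

    Returns
    -------
    covariates : DataFrame, one row per subject, indexed by subject id.
    targets : DataFrame with columns ``suv_mean`` and ``suv_sd`` — each
        subject's latent background liver SUV mean and SD (both floored at a
        small positive constant).
    labels : Series of {"normal", "abnormal"}; the ``round(fraction * n)``
        abnormal subjects occupy the last rows (they are appended to the
        screening cohort, never used for training).
    """
    config.validate()
    n = config.n_subjects
    rng = np.random.default_rng(config.seed)
    ids = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    covariates = _draw_covariates(config, n, rng)
    covariates.index = ids

    mu = np.full(n, config.true_mean_intercept)
    for name, coef in config.true_mean_coefficients.items():
        if name not in covariates.columns:
            raise ValueError(f"true coefficient on unknown covariate {name!r}")
        mu = mu + coef * covariates[name].to_numpy()
    mu = mu + config.residual_sd_mean * rng.standard_normal(n)
    sd = (config.true_sd_intercept
          + config.true_sd_weight_slope * covariates["weight"].to_numpy()
          + config.residual_sd_sd * rng.standard_normal(n))
    targets = pd.DataFrame(
        {"suv_mean": np.maximum(mu, SUV_FLOOR), "suv_sd": np.maximum(sd, SUV_FLOOR)},
        index=ids)

    n_abn = int(round(config.abnormal_fraction * n))
    labels = pd.Series(["normal"] * n, index=ids, name="label")
    if n_abn:
        labels.iloc[n - n_abn:] = "abnormal"
    return covariates, targets, labels


def _ellipsoid_mask(grid_shape: Sequence[int],
                    voxel_size_mm: Sequence[float],
                    semi_axes_mm: Sequence[float]) -> np.ndarray:
    shape = tuple(int(s) for s in grid_shape)
    vox = np.asarray(voxel_size_mm, dtype=float)
    semi = np.asarray(semi_axes_mm, dtype=float)
    if ((semi / vox) >= np.asarray(shape) / 2.0).any():
        raise ValueError(
            f"grid {shape} too small for ellipsoid semi-axes {tuple(semi)} mm "
            f"at voxel size {tuple(vox)} mm")
    center = (np.asarray(shape) - 1) / 2.0
    axes = [ (np.arange(s) - c) * v for s, c, v in zip(shape, center, vox) ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij", sparse=True)
    return (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0


_MASK_CACHE: dict[tuple, np.ndarray] = {}


def _cached_ellipsoid_mask(grid_shape, voxel_size_mm, semi_axes_mm) -> np.ndarray:
    key = (tuple(grid_shape), tuple(voxel_size_mm), tuple(semi_axes_mm))
    if key not in _MASK_CACHE:
        _MASK_CACHE[key] = _ellipsoid_mask(grid_shape, voxel_size_mm, semi_axes_mm)
    return _MASK_CACHE[key]


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0, by exact resampling.

    At liver SUV scale (mean ~2, SD ~0.4) the negative tail has probability
    ~1e-7, so resampling terminates immediately in practice.
    """
    out = mean + sd * rng.standard_normal(size)
    bad = out < 0
    while bad.any():
        out[bad] = mean + sd * rng.standard_normal(int(bad.sum()))
        bad = out < 0
    return out


def _place_lesions(mask: np.ndarray, lesions: LesionSpec,
                   voxel_size_mm: Sequence[float],
                   rng: np.random.Generator,
                   max_retries: int = 100) -> list[dict]:
    """Pick lesion centers at least radius+margin inside the mask boundary."""
    vox = np.asarray(voxel_size_mm, dtype=float)
    clearance = lesions.radius_mm + lesions.placement_margin_mm
    idx = np.argwhere(mask)
    coords_mm = idx * vox  # voxel-center physical coordinates
    boundary = np.argwhere(mask & ~_erode_once(mask))
    if len(boundary) == 0:  # mask touches nothing: treat all mask as interior
        eligible = idx
    else:
        # distance from every in-mask voxel to the nearest boundary voxel,
        # computed in physical mm (anisotropic voxels)
        from scipy.spatial import cKDTree

        tree = cKDTree(boundary * vox)
        dist, _ = tree.query(coords_mm, k=1)
        eligible = idx[dist >= clearance]
    if len(eligible) == 0:
        raise RuntimeError(
            f"no voxel admits a lesion of radius {lesions.radius_mm} mm with "
            f"margin {lesions.placement_margin_mm} mm inside this mask")
    placed: list[dict] = []
    for _ in range(lesions.n_lesions):
        for attempt in range(max_retries):
            center = eligible[rng.integers(len(eligible))]
            # avoid stacking two lesions on the same center
            if all(not np.array_equal(center, p["center_voxel"]) for p in placed):
                break
        else:
            raise RuntimeError("lesion placement failed after bounded retries")
        placed.append({
            "center_voxel": center.copy(),
            "center_mm": (center * vox).tolist(),
            "radius_mm": lesions.radius_mm,
            "contrast": lesions.contrast,
        })
    return placed


def _erode_once(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    return ndimage.binary_erosion(mask)


def generate_liver_volume(
    suv_mean: float,
    suv_sd: float,
    lesions: LesionSpec | None = None,
    grid_shape: Sequence[int] = DEFAULT_GRID_SHAPE,
    voxel_size_mm: Sequence[float] = DEFAULT_VOXEL_SIZE_MM,
    semi_axes_mm: Sequence[float] = DEFAULT_LIVER_SEMI_AXES_MM,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
) -> tuple[LiverVolume, list[dict]]:
    """Simulate one subject's liver-masked PET volume.

    An ellipsoidal liver (default semi-axes 60 x 45 x 40 mm) centered in the
    grid, in-mask voxels i.i.d. Normal(``suv_mean``, ``suv_sd``) truncated at
    0, zeros outside. If ``lesions`` is given, spheres of ``radius_mm`` are
    placed fully inside the mask and their voxels raised by ``contrast``.

    Returns the volume and the lesion ground-truth list
    (center voxel/mm, radius, contrast).
    """
    if suv_sd <= 0:
        raise ValueError(f"suv_sd must be > 0, got {suv_sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _cached_ellipsoid_mask(grid_shape, voxel_size_mm, semi_axes_mm)
    suv = np.zeros(mask.shape, dtype=float)
    suv[mask] = _truncated_normal(suv_mean, suv_sd, int(mask.sum()), rng)

    ground_truth: list[dict] = []
    if lesions is not None and lesions.n_lesions > 0:
        lesions.validate()
        ground_truth = _place_lesions(mask, lesions, voxel_size_mm, rng)
        vox = np.asarray(voxel_size_mm, dtype=float)
        center_grid = [np.arange(s) * v for s, v in zip(mask.shape, vox)]
        xx, yy, zz = np.meshgrid(*center_grid, indexing="ij", sparse=True)
        for lesion in ground_truth:
            cx, cy, cz = lesion["center_mm"]
            inside = ((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
                      <= lesions.radius_mm ** 2)
            suv[inside] += lesions.contrast
            lesion["n_voxels"] = int(inside.sum())

    volume = LiverVolume(suv=suv, mask=mask.copy(),
                         voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
                         subject_id=subject_id)
    return volume, ground_truth


def normalization_benefit_config(n_subjects: int, abnormal_fraction: float,
                                 seed: int = 0) -> CohortConfig:
    """Cohort where the background SUV mean varies strongly with covariates.

    Mean-model slopes are doubled so the covariate-driven spread of the true
    background mean is ~0.23 SUV, and subject-level SD noise is shrunk to
    0.02 so the study isolates the effect of normalizing the mean. This is the
    regime in which per-subject normalization should beat the raw SUV maximum.
    """
    coeffs = {k: 2.0 * v for k, v in DEFAULT_MEAN_COEFFICIENTS.items()}
    return CohortConfig(
        n_subjects=n_subjects,
        abnormal_fraction=abnormal_fraction,
        true_mean_coefficients=coeffs,
        true_mean_intercept=DEFAULT_MEAN_INTERCEPT - 1.14,  # keep mean SUV ~2.06
        residual_sd_sd=0.02,
        seed=seed,
    )
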