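"""End-to-end analysis: simulate -> fit healthy-only models -> Z-maps -> ROC.

The pipeline mirrors the screening-study protocol: healthy subjects are split
at random into equal train/test halves; abnormal subjects are appended to the
test side only and never seen during training; the SUV-mean and SUV-SD models
are fitted on the training half (responses measured from the liver-masked
volumes); every evaluation subject then gets covariate-predicted E(Y), SD(Y),
a Z-score map, and per-subject SUV_max / Z_max scores feeding the patient-wise
ROC comparison.

A single integer seed fixes the cohort, the split, the CV folds and every
volume, so two runs with the same config produce byte-identical manifests.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .evaluation import compare_normalization
from .lasso import LiverSuvLasso
from .synthetic import (CohortConfig, LesionSpec, generate_cohort,
                        generate_liver_volume, DEFAULT_GRID_SHAPE,
                        DEFAULT_LIVER_SEMI_AXES_MM, DEFAULT_VOXEL_SIZE_MM)
from .zscore import SD_FLOOR, compute_zscore_map, score_subject

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("livernorm")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage (and subject, if any)."""


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``seed`` is the master seed: it re-seeds the cohort, the train/test
    split, the CV folds and every subject's volume. ``train_fraction``
    defaults to the study's equal split of the healthy cohort.
    """

    mode: str = "synthetic"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    train_fraction: float = 0.5
    lambda_target_support: int = 10
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 2
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM
    liver_semi_axes_mm: tuple[float, float, float] = DEFAULT_LIVER_SEMI_AXES_MM
    seed: int = 0
    output_dir: str = "livernorm_run"
    save_volumes: bool = False
    save_zmaps: bool = False
    # files mode
    covariates_csv: str | None = None
    volumes_dir: str | None = None

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode == "synthetic":
            self.cohort.validate()
            self.lesion.validate()
        else:
            for p in (self.covariates_csv, self.volumes_dir):
                if p is None or not Path(p).exists():
                    raise ValueError(f"files mode needs existing path, got {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        if "lesion" in raw:
            raw["lesion"] = LesionSpec(**raw["lesion"])
        for key in ("grid_shape", "voxel_size_mm", "liver_semi_axes_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = copy.deepcopy(vars(self))
        d["cohort"] = {k: (dict(v) if isinstance(v, dict) or hasattr(v, "items")
                           else v)
                       for k, v in vars(self.cohort).items()}
        d["lesion"] = dict(vars(self.lesion))
        for key in ("grid_shape", "voxel_size_mm", "liver_semi_axes_mm"):
            d[key] = list(d[key])
        return d

    def replace(self, **kwargs) -> "PipelineConfig":
        new = copy.deepcopy(self)
        for k, v in kwargs.items():
            if not hasattr(new, k):
                raise AttributeError(k)
            setattr(new, k, v)
        return new


def _stage(name: str, subject_id: str | None = None):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                who = f" (subject {subject_id})" if subject_id else ""
                raise PipelineError(f"stage '{name}'{who}: {exc}") from exc
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def _subject_rng_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _derive_seeds(seed: int) -> dict[str, int]:
    root = np.random.SeedSequence(seed)
    cohort_ss, split_ss, volume_ss, cv_ss = root.spawn(4)
    to_int = lambda ss: int(ss.generate_state(1)[0] % (2**31))
    return {"cohort": to_int(cohort_ss), "split": to_int(split_ss),
            "volumes": to_int(volume_ss), "cv": to_int(cv_ss)}


def _synthetic_volume(config: PipelineConfig, idx: int, subject_id: str,
                      targets: pd.DataFrame, labels: pd.Series,
                      volume_seeds) -> tuple:
    lesions = config.lesion if labels.loc[subject_id] == "abnormal" else None
    return generate_liver_volume(
        suv_mean=float(targets.loc[subject_id, "suv_mean"]),
        suv_sd=float(targets.loc[subject_id, "suv_sd"]),
        lesions=lesions,
        grid_shape=config.grid_shape,
        voxel_size_mm=config.voxel_size_mm,
        semi_axes_mm=config.liver_semi_axes_mm,
        seed=np.random.default_rng(volume_seeds[idx]),
        subject_id=subject_id)


def _load_volume(config: PipelineConfig, subject_id: str):
    d = Path(config.volumes_dir)
    for ext in (".nii.gz", ".nii"):
        suv_p = d / f"{subject_id}_suv{ext}"
        mask_p = d / f"{subject_id}_mask{ext}"
        if suv_p.exists() and mask_p.exists():
            return lio.read_volume(suv_p, mask_p, subject_id=subject_id), []
    raise FileNotFoundError(f"no SUV/mask volume pair for {subject_id} in {d}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk).

    The manifest records the config, the derived seeds, the train/test subject
    ids, the fitted models, the evaluation report and a SHA-256 hash of every
    written artifact — enough to re-run bit-identically.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)

    # ------------------------------------------------------------------ cohort
    with _stage("cohort"):
        if config.mode == "synthetic":
            cohort_cfg = config.cohort.replace(seed=seeds["cohort"])
            covariates, targets, labels = generate_cohort(cohort_cfg)
        else:
            covariates, labels = lio.read_covariates(config.covariates_csv)
            if labels is None:
                raise ValueError("files-mode covariate CSV needs a 'label' column")
            targets = None
        log.info("stage=cohort n=%d abnormal=%d", len(covariates),
                 int((labels == "abnormal").sum()))

    # ------------------------------------------------------------------- split
    with _stage("split"):
        healthy = labels.index[labels == "normal"]
        abnormal = labels.index[labels == "abnormal"]
        rng = np.random.default_rng(seeds["split"])
        order = rng.permutation(len(healthy))
        n_train = int(round(config.train_fraction * len(healthy)))
        train_ids = healthy[order[:n_train]].sort_values()
        test_ids = healthy[order[n_train:]].sort_values()
        eval_ids = test_ids.append(abnormal)
        if len(train_ids) < 4:
            raise ValueError("too few healthy training subjects")
        log.info("stage=split train=%d test=%d abnormal=%d",
                 len(train_ids), len(test_ids), len(abnormal))

    # ------------------------------------------------ observed liver statistics
    volume_seeds = (_subject_rng_seeds(seeds["volumes"], len(covariates))
                    if config.mode == "synthetic" else None)
    pos = {sid: i for i, sid in enumerate(covariates.index)}

    def get_volume(sid: str):
        if config.mode == "synthetic":
            return _synthetic_volume(config, pos[sid], sid, targets, labels,
                                     volume_seeds)
        return _load_volume(config, sid)

    obs = {}
    with _stage("measure"):
        for sid in covariates.index:
            with _stage("measure", sid):
                vol, _ = get_volume(sid)
                vals = vol.suv[vol.mask]
                obs[sid] = (float(vals.mean()), float(vals.std()),
                            float(vals.max()))
        observed = pd.DataFrame.from_dict(
            obs, orient="index", columns=["suv_mean", "suv_sd", "suv_max"])
        observed.index.name = "subject_id"

    # --------------------------------------------------------------------- fit
    with _stage("fit"):
        X_train = covariates.loc[train_ids]
        fitted = {}
        cv_tables = {}
        for kind in ("mean", "sd"):
            y = observed.loc[train_ids, f"suv_{kind}"]
            model = LiverSuvLasso(y, X_train, kind=kind)
            path = model.fit_path(n_lambdas=config.n_lambdas,
                                  lambda_min_ratio=config.lambda_min_ratio)
            res = path.select_by_support(config.lambda_target_support)
            cv_tables[kind] = model.cross_validate(
                path.lambdas, k=config.cv_folds, seed=seeds["cv"])
            fitted[kind] = res
            log.info("stage=fit kind=%s lambda=%.3g support=%d",
                     kind, res.alpha, res.df_model)

    # ----------------------------------------------------------------- predict
    with _stage("predict"):
        X_eval = covariates.loc[eval_ids]
        e_y = pd.Series(fitted["mean"].predict(X_eval), index=eval_ids)
        sd_y = pd.Series(fitted["sd"].predict(X_eval), index=eval_ids)
        n_floored = int((sd_y <= SD_FLOOR).sum())
        if n_floored:
            log.warning("predicted SD at/below %g for %d subject(s); flooring",
                        SD_FLOOR, n_floored)
            sd_y = sd_y.clip(lower=2 * SD_FLOOR)

    # ------------------------------------------------------------------- score
    scores = []
    zmap_dir = out / "zmaps"
    with _stage("score"):
        for sid in eval_ids:
            with _stage("score", sid):
                vol, _ = get_volume(sid)
                sc = score_subject(vol, float(e_y[sid]), float(sd_y[sid]),
                                   label=str(labels.loc[sid]))
                scores.append(sc)
                if config.save_zmaps:
                    zmap_dir.mkdir(exist_ok=True)
                    zm = compute_zscore_map(vol, float(e_y[sid]), float(sd_y[sid]))
                    lio.write_zscore_map(zmap_dir / f"{sid}_zmap.nii.gz", zm,
                                         vol.voxel_size_mm)
                if config.save_volumes:
                    vdir = out / "volumes"
                    vdir.mkdir(exist_ok=True)
                    lio.write_volume(vdir / f"{sid}_suv.nii.gz", vol,
                                     vdir / f"{sid}_mask.nii.gz")

    # ---------------------------------------------------------------- evaluate
    with _stage("evaluate"):
        score_df = pd.DataFrame([s.as_dict() for s in scores])
        report = compare_normalization(score_df)
        lio.write_json(out / "report.json",
                       {k: v for k, v in report.items()
                        if not k.startswith("roc_")})
        report["roc_suv"].as_frame().to_csv(out / "roc_suv.tsv", sep="\t",
                                            index=False)
        report["roc_z"].as_frame().to_csv(out / "roc_z.tsv", sep="\t",
                                          index=False)
        log.info("stage=evaluate auroc_suv=%.3f auroc_z=%.3f p=%.3g",
                 report["auroc_suv"], report["auroc_z"], report["p_value"])

    # ------------------------------------------------------------------- write
    with _stage("write"):
        lio.write_covariates(out / "covariates.csv", covariates, labels)
        observed.to_csv(out / "observed_stats.csv", float_format="%.17g")
        fitted["mean"].to_json(out / "mean_model.json")
        fitted["sd"].to_json(out / "sd_model.json")
        lio.write_scores(out / "scores.tsv", scores)
        for kind in ("mean", "sd"):
            cv_tables[kind].to_csv(out / f"cv_{kind}.tsv", sep="\t",
                                   float_format="%.17g")
        artifact_names = ["covariates.csv", "observed_stats.csv",
                          "mean_model.json", "sd_model.json", "scores.tsv",
                          "cv_mean.tsv", "cv_sd.tsv", "report.json",
                          "roc_suv.tsv", "roc_z.tsv"]
        manifest = {
            "seed": config.seed,
            "derived_seeds": seeds,
            "config": config.to_dict(),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "n_abnormal": len(abnormal),
            "train_ids": list(map(str, train_ids)),
            "test_ids": list(map(str, eval_ids)),
            "models": {k: fitted[k].to_dict() for k in fitted},
            "report": {k: v for k, v in report.items()
                       if not k.startswith("roc_")},
            "artifacts": {name: lio.sha256_of(out / name)
                          for name in artifact_names},
        }
        lio.write_json(out / "manifest.json", manifest)
    return manifest
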