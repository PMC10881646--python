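"""Patient-wise ROC analysis and DeLong's test for correlated AUROCs.

Each subject contributes one score (SUV_max or Z_max) and one label; higher
scores indicate abnormality. The AUROC is computed as the Mann-Whitney
statistic with midrank tie handling, and two scores measured on the same
subjects are compared with DeLong's structural-components (placement-value)
test for correlated ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

__all__ = ["RocCurve", "DeLongResult", "roc_curve", "auroc", "delong_test",
           "compare_normalization"]


@dataclass
class RocCurve:
    """Operating points swept over decreasing score thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float
    n_pos: int
    n_neg: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


@dataclass
class DeLongResult:
    auroc_a: float
    auroc_b: float
    delta: float
    variance_delta: float
    z_statistic: float
    p_value: float
    n_pos: int
    n_neg: int


def _validate_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if np.isnan(scores).any():
        raise ValueError("NaN score")
    if labels.dtype.kind == "O":
        labels = labels.astype(str)
    if labels.dtype.kind in "US":
        pos = labels == "abnormal"
        known = pos | (labels == "normal")
        if not known.all():
            raise ValueError("labels must be 'normal'/'abnormal' or 0/1")
    else:
        pos = labels.astype(bool)
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present")
    return scores, pos


def roc_curve(scores, labels) -> RocCurve:
    """Patient-wise ROC: one operating point per distinct score plus (0,0).

    Thresholds decrease; a subject is called abnormal when score >= threshold,
    so ties share an operating point. Starts at sensitivity 0 / specificity 1
    and ends at sensitivity 1 / specificity 0.
    """
    scores, pos = _validate_scores(scores, labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-scores, kind="mergesort")
    s, p = scores[order], pos[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tp = np.cumsum(p)[distinct]
    fp = np.cumsum(~p)[distinct]
    thresholds = np.r_[np.inf, s[distinct]]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, 1.0 - fp / n_neg]
    return RocCurve(thresholds=thresholds, sensitivity=sens,
                    specificity=spec, auroc=auroc(scores, pos),
                    n_pos=n_pos, n_neg=n_neg)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC with midrank ties.

    Equals (correctly ordered positive-negative pairs + half the tied
    pairs) / (n_pos * n_neg), i.e. the probability a random abnormal subject
    outscores a random normal one.
    """
    scores, pos = _validate_scores(scores, labels)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # midranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _placement_values(scores: np.ndarray, pos: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components.

    v10[i] = P-hat(positive i outscores a random negative); v01[j] likewise
    for negatives, with midrank (half) credit for ties. Their means both equal
    the AUROC.
    """
    sp = scores[pos][:, None]
    sn = scores[~pos][None, :]
    psi = (sp > sn).astype(float) + 0.5 * (sp == sn)
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong's test comparing two correlated AUROCs on the same subjects.

    Var(A_a - A_b) = var(v10_a - v10_b)/m + var(v01_a - v01_b)/n with sample
    covariances (divisor m-1, n-1); the two-sided p-value uses the normal
    approximation. A degenerate variance with delta = 0 yields p = 1.
    """
    scores_a, pos = _validate_scores(scores_a, labels)
    scores_b, pos_b = _validate_scores(scores_b, labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must have equal length")
    m, n = int(pos.sum()), int((~pos).sum())
    if m < 2 or n < 2:
        raise ValueError("DeLong's test needs >= 2 subjects per class")
    v10_a, v01_a, a_a = _placement_values(scores_a, pos)
    v10_b, v01_b, a_b = _placement_values(scores_b, pos)
    delta = a_a - a_b
    d10 = v10_a - v10_b
    d01 = v01_a - v01_b
    var = float(d10.var(ddof=1) / m + d01.var(ddof=1) / n)
    if var <= 0:
        if abs(delta) < 1e-12:
            return DeLongResult(a_a, a_b, delta, 0.0, 0.0, 1.0, m, n)
        raise ValueError(
            "zero DeLong variance with nonzero AUROC difference: "
            "inconsistent input")
    z = delta / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongResult(auroc_a=a_a, auroc_b=a_b, delta=delta,
                        variance_delta=var, z_statistic=float(z),
                        p_value=p, n_pos=m, n_neg=n)


def compare_normalization(subject_scores: pd.DataFrame) -> dict:
    """Head-to-head patient-wise comparison of Z_max against SUV_max.

    ``subject_scores`` needs columns ``suv_max``, ``z_max`` and ``label``.
    Returns a machine-readable report with both ROC curves, both AUROCs, the
    DeLong result and the verdict (which score wins).
    """
    for col in ("suv_max", "z_max", "label"):
        if col not in subject_scores.columns:
            raise KeyError(f"subject-score table lacks column {col!r}")
    labels = subject_scores["label"].to_numpy()
    suv = subject_scores["suv_max"].to_numpy(dtype=float)
    z = subject_scores["z_max"].to_numpy(dtype=float)
    roc_suv = roc_curve(suv, labels)
    roc_z = roc_curve(z, labels)
    dl = delong_test(z, suv, labels)
    if dl.delta > 0:
        verdict = "z_max"
    elif dl.delta < 0:
        verdict = "suv_max"
    else:
        verdict = "tie"
    return {
        "auroc_suv": roc_suv.auroc,
        "auroc_z": roc_z.auroc,
        "delta": dl.delta,
        "z_statistic": dl.z_statistic,
        "p_value": dl.p_value,
        "n_pos": dl.n_pos,
        "n_neg": dl.n_neg,
        "verdict": verdict,
        "roc_suv": roc_suv,
        "roc_z": roc_z,
    }
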