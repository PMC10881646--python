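"""L1-penalized linear regression of liver SUV statistics on covariates.

The model solved here is

    min_{b0, b}  (1/(2n)) * ||y - b0 - X b||_2^2  +  lambda * ||b||_1

by cyclic coordinate descent with soft-thresholding, an unpenalized intercept
and internally standardized predictors (mean 0, SD 1, divisor n). Coefficients
are reported on the original covariate scale. The penalty ``lambda`` lives on
the 1/(2n) objective scale; the equivalent penalty for the un-normalized
residual-sum-of-squares objective is ``2 n lambda`` and is reported alongside.

Lambda is chosen either by the support-size heuristic (largest penalty keeping
roughly a target number of variables, the clinical-usefulness criterion) or by
k-fold cross-validation, both exposed on the fitted path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Standardization",
    "standardize",
    "lambda_max",
    "soft_threshold",
    "LiverSuvLasso",
    "LassoResults",
    "LassoPath",
    "select_lambda_by_support",
    "lasso_fit",
]

COEF_TOL = 1e-7          # convergence: max |coef change| over a full sweep
KKT_TOL = 1e-6
MAX_SWEEPS = 100_000


class ConvergenceError(RuntimeError):
    """Coordinate descent did not converge; carries the last iterate."""

    def __init__(self, msg: str, last_beta: np.ndarray):
        super().__init__(msg)
        self.last_beta = last_beta


@dataclass(frozen=True)
class Standardization:
    """Per-variable center/scale used internally (population SD, divisor n)."""

    center: np.ndarray
    scale: np.ndarray
    names: tuple[str, ...]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def inverse(self, X_std: np.ndarray) -> np.ndarray:
        return X_std * self.scale + self.center


def _as_matrix(X, names: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if names is None:
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    return X, tuple(map(str, names))


def standardize(X, names: Sequence[str] | None = None
                ) -> tuple[np.ndarray, Standardization]:
    """Center and scale each column to mean 0, SD 1 (divisor n).

    Raises on zero-variance columns, naming the offending variable.
    """
    values, names = _as_matrix(X, names)
    if np.isnan(values).any():
        raise ValueError("design matrix contains NaN")
    center = values.mean(axis=0)
    scale = values.std(axis=0)  # population SD
    dead = np.flatnonzero(scale <= 0)
    if dead.size:
        raise ValueError(
            "zero-variance column(s): " + ", ".join(names[j] for j in dead))
    params = Standardization(center=center, scale=scale, names=names)
    return params.transform(values), params


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every slope is zero: max_j |x_j' yc| / n.

    ``y`` is centered internally; ``X_std`` must be standardized.
    """
    X_std = np.asarray(X_std, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_std.shape[0] != y.shape[0]:
        raise ValueError(
            f"X has {X_std.shape[0]} rows but y has {y.shape[0]}")
    yc = y - y.mean()
    return float(np.abs(X_std.T @ yc).max() / len(y)) if X_std.shape[1] else 0.0


def soft_threshold(x: float, t: float) -> float:
    return float(np.sign(x) * max(abs(x) - t, 0.0))


def _coordinate_descent(Xs: np.ndarray, yc: np.ndarray, lam: float,
                        beta0: np.ndarray | None = None,
                        tol: float = COEF_TOL,
                        max_sweeps: int = MAX_SWEEPS) -> np.ndarray:
    """Cyclic coordinate descent on standardized columns (x_j'x_j / n = 1)."""
    n, p = Xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    r = yc - Xs @ beta
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = (Xs[:, j] @ r) / n + bj
            new = soft_threshold(rho, lam)
            if new != bj:
                r += Xs[:, j] * (bj - new)
                beta[j] = new
                delta = max(delta, abs(new - bj))
        if delta < tol:
            return beta
    raise ConvergenceError(
        f"coordinate descent did not converge in {max_sweeps} sweeps "
        f"(lambda={lam:g})", beta)


class LiverSuvLasso:
    """L1-penalized linear model of a per-subject liver SUV statistic.

    Parameters
    ----------
    endog : 1-D response (per-subject liver SUV mean, or SUV SD).
    exog : n x p covariate matrix or DataFrame (blood tests + demographics);
        an intercept is always included and never penalized — do not add a
        constant column.
    var_names : column labels when ``exog`` is a bare array.
    kind : ``"mean"`` or ``"sd"`` — which SUV statistic is modeled. For
        ``"sd"`` every response must be positive.
    """

    def __init__(self, endog, exog, var_names: Sequence[str] | None = None,
                 kind: str = "mean"):
        if kind not in ("mean", "sd"):
            raise ValueError(f"kind must be 'mean' or 'sd', got {kind!r}")
        y = np.asarray(endog, dtype=float).ravel()
        if not np.isfinite(y).all():
            raise ValueError("response contains non-finite values")
        if kind == "sd" and (y <= 0).any():
            raise ValueError("SUV-SD responses must all be > 0")
        X_std, params = standardize(exog, var_names)
        if len(y) != X_std.shape[0]:
            raise ValueError("endog/exog length mismatch")
        if len(y) < 2:
            raise ValueError("need at least 2 subjects")
        self.kind = kind
        self.endog = y
        self.exog_std = X_std
        self.standardization = params
        self.var_names = params.names
        self.nobs = len(y)
        self._y_mean = float(y.mean())
        self._yc = y - self._y_mean

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       covariates: Sequence[str] | None = None,
                       kind: str | None = None) -> "LiverSuvLasso":
        covariates = ([c for c in data.columns if c != response]
                      if covariates is None else list(covariates))
        if kind is None:
            kind = "sd" if "sd" in response else "mean"
        return cls(data[response], data[covariates], kind=kind)

    @property
    def lambda_max(self) -> float:
        return lambda_max(self.exog_std, self.endog)

    def fit(self, alpha: float, start_params: np.ndarray | None = None
            ) -> "LassoResults":
        """Solve at penalty ``alpha`` (1/(2n) objective scale)."""
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if alpha == 0.0:
            # exact minimizer of the same objective; requires full column rank
            beta_std, *_ = np.linalg.lstsq(self.exog_std, self._yc, rcond=None)
        elif alpha >= self.lambda_max:
            # zero vector is optimal by the KKT bound; avoids leaving
            # last-ulp coefficients when alpha equals lambda_max exactly
            beta_std = np.zeros(self.exog_std.shape[1])
        else:
            beta_std = _coordinate_descent(self.exog_std, self._yc, alpha,
                                           beta0=start_params)
        return LassoResults(self, alpha, beta_std)

    def fit_path(self, n_lambdas: int = 100, lambda_min_ratio: float = 1e-3
                 ) -> "LassoPath":
        """Fit a log-spaced penalty path from lambda_max down, warm-started."""
        if n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        lmax = self.lambda_max
        if lmax <= 0:
            raise ValueError("response is orthogonal to all predictors")
        lambdas = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambdas)
        results, beta = [], None
        for lam in lambdas:
            res = self.fit(lam, start_params=beta)
            beta = res.params_std
            results.append(res)
        return LassoPath(lambdas=lambdas, results=results)

    def cross_validate(self, alphas: Sequence[float], k: int = 2,
                       seed: int = 0) -> pd.DataFrame:
        """k-fold CV of prediction MSE over ``alphas`` (seeded random split).

        Returns a DataFrame indexed by alpha with columns ``cv_mse`` (mean of
        fold MSEs) and ``cv_se`` (standard error over folds).
        """
        if k < 2:
            raise ValueError("k must be >= 2")
        if self.nobs < 2 * k:
            raise ValueError(f"need at least {2 * k} subjects for {k}-fold CV")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.nobs)
        folds = np.array_split(perm, k)
        X_orig = self.standardization.inverse(self.exog_std)
        errors = np.empty((k, len(alphas)))
        for i, fold in enumerate(folds):
            if len(fold) < 2:
                raise ValueError("fold with fewer than 2 subjects")
            train = np.setdiff1d(perm, fold)
            sub = LiverSuvLasso(self.endog[train], X_orig[train],
                                var_names=self.var_names, kind=self.kind)
            beta = None
            for j, alpha in enumerate(alphas):
                res = sub.fit(alpha, start_params=beta)
                beta = res.params_std
                pred = res.predict(X_orig[fold])
                errors[i, j] = np.mean((self.endog[fold] - pred) ** 2)
        return pd.DataFrame(
            {"cv_mse": errors.mean(axis=0),
             "cv_se": errors.std(axis=0, ddof=1) / np.sqrt(k)},
            index=pd.Index(alphas, name="alpha"))


class LassoResults:
    """Fitted L1 model: original-scale coefficients, support, diagnostics."""

    def __init__(self, model: LiverSuvLasso, alpha: float,
                 params_std: np.ndarray):
        self.model = model
        self.alpha = float(alpha)
        self.params_std = np.asarray(params_std, dtype=float)
        s = model.standardization
        coefs = self.params_std / s.scale
        self.params = pd.Series(coefs, index=list(s.names), name="coef")
        self.intercept = float(model._y_mean - coefs @ s.center)
        self.kind = model.kind
        self.nobs = model.nobs

    # -- basic quantities ---------------------------------------------------
    @property
    def alpha_rss_scale(self) -> float:
        """Penalty on the literal ||y - Xb||^2 + lambda*||b||_1 scale."""
        return 2.0 * self.nobs * self.alpha

    @property
    def support(self) -> list[str]:
        return [n for n, c in self.params.items() if c != 0.0]

    @property
    def df_model(self) -> int:
        return int((self.params_std != 0).sum())

    def predict(self, exog) -> np.ndarray:
        """intercept + X @ coef on the original covariate scale."""
        if isinstance(exog, pd.DataFrame):
            missing = [n for n in self.support if n not in exog.columns]
            if missing:
                raise KeyError(
                    "covariates missing for prediction: " + ", ".join(missing))
            X = exog.reindex(columns=list(self.params.index), fill_value=0.0)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
            if X.shape[1] != len(self.params):
                raise ValueError("wrong number of covariate columns")
        return self.intercept + X @ self.params.to_numpy()

    @property
    def fittedvalues(self) -> np.ndarray:
        return (self.model._y_mean
                + self.model.exog_std @ self.params_std)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def objective(self) -> float:
        rss = float(self.resid @ self.resid)
        return rss / (2 * self.nobs) + self.alpha * float(
            np.abs(self.params_std).sum())

    # -- optimality ----------------------------------------------------------
    def kkt_violation(self) -> float:
        """Max violation of the subgradient optimality conditions.

        For zero coefficients |x_j' r|/n must not exceed alpha; for active
        ones it must equal alpha with matching sign. Residuals are taken on
        the standardized scale (where the problem is solved).
        """
        r = self.model._yc - self.model.exog_std @ self.params_std
        g = self.model.exog_std.T @ r / self.nobs
        active = self.params_std != 0
        viol = 0.0
        if (~active).any():
            viol = max(viol, float(np.abs(g[~active]).max() - self.alpha))
        if active.any():
            viol = max(viol, float(np.abs(
                g[active] - self.alpha * np.sign(self.params_std[active])).max()))
        return max(viol, 0.0)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"L1-penalized linear model of liver SUV {self.kind}",
            f"  n = {self.nobs}, p = {len(self.params)}, "
            f"support = {self.df_model}",
            f"  lambda = {self.alpha:.6g} (1/(2n) scale)"
            f" = {self.alpha_rss_scale:.6g} (RSS scale)",
            f"  intercept = {self.intercept:.6g}",
            "  nonzero coefficients (original covariate scale):",
        ]
        for name in self.support:
            lines.append(f"    {name:<22s} {self.params[name]: .6g}")
        if not self.support:
            lines.append("    (none)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "intercept": self.intercept,
            "coefficients": {n: float(c) for n, c in self.params.items()},
            "lambda_internal": self.alpha,
            "lambda_rss_scale": self.alpha_rss_scale,
            "standardization": {
                "center": self.model.standardization.center.tolist(),
                "scale": self.model.standardization.scale.tolist(),
                "names": list(self.model.standardization.names),
            },
            "n_train": self.nobs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class FrozenLassoModel:
    """A deserialized fitted model: enough to predict, nothing more."""

    kind: str
    intercept: float
    coefficients: pd.Series
    lambda_internal: float
    n_train: int

    @classmethod
    def from_json(cls, path) -> "FrozenLassoModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], intercept=float(d["intercept"]),
                   coefficients=pd.Series(d["coefficients"], dtype=float),
                   lambda_internal=float(d["lambda_internal"]),
                   n_train=int(d["n_train"]))

    @property
    def support(self) -> list[str]:
        return [n for n, c in self.coefficients.items() if c != 0.0]

    def predict(self, exog: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.support if n not in exog.columns]
        if missing:
            raise KeyError(
                "covariates missing for prediction: " + ", ".join(missing))
        X = exog.reindex(columns=list(self.coefficients.index), fill_value=0.0)
        return self.intercept + X.to_numpy(dtype=float) @ self.coefficients.to_numpy()


@dataclass
class LassoPath:
    """Regularization path: decreasing penalties and the fit at each one."""

    lambdas: np.ndarray
    results: list[LassoResults]

    @property
    def support_sizes(self) -> np.ndarray:
        return np.array([r.df_model for r in self.results])

    def select_by_support(self, target_support: int) -> LassoResults:
        return select_lambda_by_support(self, target_support)


def select_lambda_by_support(path: LassoPath, target_support: int
                             ) -> LassoResults:
    """Largest penalty whose support reaches ``target_support`` variables.

    If no penalty on the path reaches the target, the fit with support size
    closest to it (ties broken toward the larger penalty) is returned.
    """
    if not path.results:
        raise ValueError("empty lambda path")
    sizes = path.support_sizes
    reached = np.flatnonzero(sizes >= target_support)
    if reached.size:
        # lambdas are decreasing: first index reaching the target = largest
        return path.results[int(reached[0])]
    best = int(np.argmin(np.abs(sizes - target_support)))  # first = larger lam
    return path.results[best]


def lasso_fit(X, y, alpha: float, var_names: Sequence[str] | None = None,
              kind: str = "mean") -> LassoResults:
    """One-call fit at a single penalty (see :class:`LiverSuvLasso`)."""
    return LiverSuvLasso(y, X, var_names=var_names, kind=kind).fit(alpha)
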