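"""Two-part model for the ceiling-inflated EQ-5D index.

A large share of general-population respondents report full health (state
11111, index exactly 1), so the index distribution has a point mass at its
ceiling. The two-part model handles this directly:

* part 1 — logistic regression for P(index = 1), fitted by Newton/IRLS with
  step-halving so the deviance decreases monotonically to convergence;
* part 2 — least squares with cluster-robust variance on the subset with
  index < 1.

Predictions combine the parts either as the expectation
E[y|x] = p̂·1 + (1−p̂)·ŷ₂ (default) or by classify-then-predict
(predict 1 when p̂ ≥ threshold, else ŷ₂).

Perfect separation in part 1 is detected (diverging coefficients /
vanishing working weights) and answered with a ridge-penalized refit plus a
warning rather than a crash.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import DesignSpec
from .ols import CLIP_RANGE, OLSFit, fit_ols, predict_ols

__all__ = ["TwoPartFit", "fit_logistic", "fit_twopart", "predict_twopart"]

_MAX_ITER = 100
_TOL = 1e-8


@dataclass
class LogisticFit:
    """Maximum-likelihood (or ridge-fallback) binary logit."""

    labels: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    deviance: float
    n_iter: int
    converged: bool
    ridge: float = 0.0
    deviance_path: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.beta):
            raise ValueError(
                f"design has {X.shape[1]} columns but the logistic part expects "
                f"{len(self.beta)} ({self.labels})"
            )
        return _sigmoid(X @ self.beta)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    labels: Sequence[str] | None = None,
    ridge: float = 0.0,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> LogisticFit:
    """Newton/IRLS logistic fit with step-halving.

    Convergence: relative log-likelihood (deviance) change below ``tol``.
    On signs of perfect separation the model is refitted with a small ridge
    penalty on the non-intercept terms and a warning is issued.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic response must be binary 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("logistic response is constant; both outcomes are required")
    labels = list(labels) if labels is not None else [f"x{j}" for j in range(k)]

    pen = np.zeros(k) if ridge == 0 else np.full(k, ridge)
    if ridge > 0:
        pen[[j for j, lab in enumerate(labels) if lab == "const"]] = 0.0

    beta = np.zeros(k)
    if "const" in labels:
        beta[labels.index("const")] = np.log(y.mean() / (1 - y.mean()))
    p = _sigmoid(X @ beta)
    dev = _deviance(y, p) + float(pen @ beta**2)
    path = [dev]

    converged = False
    for it in range(1, max_iter + 1):
        w = p * (1 - p)
        grad = X.T @ (y - p) - 2 * pen * beta
        hess = (X * w[:, None]).T @ X + 2 * np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving keeps the (penalized) deviance monotone decreasing
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            pc = _sigmoid(X @ cand)
            dc = _deviance(y, pc) + float(pen @ cand**2)
            if dc <= dev + 1e-14:
                break
            lam /= 2.0
        beta, p = cand, pc
        path.append(dc)
        if abs(dev - dc) <= tol * (abs(dev) + 1.0):
            dev = dc
            converged = True
            break
        dev = dc

    separated = (not converged and np.max(np.abs(beta)) > 30) or (
        converged and ridge == 0 and np.max(np.abs(X @ beta)) > 30
    )
    if separated and ridge == 0:
        warnings.warn(
            "possible perfect separation in the logistic part; refitting with a "
            "small ridge penalty",
            stacklevel=2,
        )
        return fit_logistic(X, y, labels, ridge=1e-4, max_iter=max_iter, tol=tol)

    w = np.clip(p * (1 - p), 1e-12, None)
    hess = (X * w[:, None]).T @ X + 2 * np.diag(pen)
    vcov = np.linalg.inv(hess)
    return LogisticFit(
        labels=labels,
        beta=beta,
        vcov=vcov,
        se=np.sqrt(np.diag(vcov)),
        deviance=float(_deviance(y, p)),
        n_iter=it,
        converged=converged,
        ridge=ridge,
        deviance_path=path,
    )


@dataclass
class TwoPartFit:
    """Fitted two-part (logistic + subset least-squares) mapping."""

    labels: list[str]
    logistic_part: LogisticFit
    ols_part: OLSFit
    spec: DesignSpec | None = None
    ceiling: float = 1.0
    n: int = 0
    n_ceiling: int = 0

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "ceiling": self.ceiling,
            "n": self.n,
            "n_ceiling": self.n_ceiling,
            "logistic": {
                "beta": self.logistic_part.beta.tolist(),
                "se": self.logistic_part.se.tolist(),
                "deviance": self.logistic_part.deviance,
                "ridge": self.logistic_part.ridge,
            },
            "ols": self.ols_part.to_dict(),
            "spec": self.spec.to_dict() if self.spec is not None else None,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_twopart(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
    spec: DesignSpec | None = None,
    ceiling: float = 1.0,
) -> TwoPartFit:
    """Fit both parts on a shared design.

    Part 1 models the indicator [y == ceiling]; part 2 is cluster-robust
    least squares on the rows with y below the ceiling. Requires observations
    on both sides of the ceiling.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    at_ceiling = y >= ceiling - 1e-12
    n_ceil = int(at_ceiling.sum())
    if n_ceil == 0:
        raise ValueError("no observations at the ceiling; a two-part model is not identified")
    if n_ceil == len(y):
        raise ValueError("every observation is at the ceiling; part 2 has no data")
    if len(y) - n_ceil < X.shape[1]:
        raise ValueError(
            f"only {len(y) - n_ceil} observations below the ceiling for "
            f"{X.shape[1]} design columns; part 2 is not estimable"
        )
    if n_ceil < 2 or len(y) - n_ceil < 2 * X.shape[1]:
        warnings.warn(
            f"degenerate ceiling split ({n_ceil} of {len(y)} at ceiling); "
            "estimates will be unstable",
            stacklevel=2,
        )

    logistic = fit_logistic(X, at_ceiling.astype(float), labels=labels)
    sub = ~at_ceiling
    sub_clusters = clusters[sub] if clusters is not None else None
    ols_part = fit_ols(X[sub], y[sub], sub_clusters, labels=labels, spec=spec)

    return TwoPartFit(
        labels=list(labels) if labels is not None else logistic.labels,
        logistic_part=logistic,
        ols_part=ols_part,
        spec=spec,
        ceiling=ceiling,
        n=len(y),
        n_ceiling=n_ceil,
    )


def predict_twopart(
    fit: TwoPartFit,
    X_new: np.ndarray,
    rule: str = "expectation",
    threshold: float = 0.5,
    clip: bool = False,
) -> np.ndarray:
    """Combine the two parts into an index prediction.

    rule="expectation": p̂·ceiling + (1−p̂)·ŷ₂ (the standard two-part mean).
    rule="classify":    ceiling where p̂ ≥ threshold, else ŷ₂.
    """
    p = fit.logistic_part.predict_proba(X_new)
    y2 = predict_ols(fit.ols_part, X_new)
    if rule == "expectation":
        pred = p * fit.ceiling + (1 - p) * y2
    elif rule == "classify":
        pred = np.where(p >= threshold, fit.ceiling, y2)
    else:
        raise ValueError(f"unknown combination rule {rule!r}; use 'expectation' or 'classify'")
    if clip:
        pred = np.clip(pred, CLIP_RANGE[0], CLIP_RANGE[1])
    return pred
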