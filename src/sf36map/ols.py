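"""OLS mapping regressions with cluster-robust (sandwich) variance.

The workhorse crosswalk estimator: ordinary least squares of the EQ-5D
index on an SF-36 design matrix, with a cluster-robust sandwich covariance
to absorb within-community / within-hospital correlation, and significance-
based backward elimination (drop the least significant term while any
robust-Wald p-value is at or above alpha).

Sandwich details. With bread B = (XᵀX)⁻¹ and meat M = Σ_g Xgᵀ eg egᵀ Xg
summed over clusters g, the covariance is c·B M B with the CR1-style
finite-sample factor c = [G/(G−1)]·[(n−1)/(n−k)]. When every observation is
its own cluster this reduces exactly to the HC1 heteroskedasticity-robust
estimator. Wald tests use the standard-normal reference by default; a
t(G−1) reference is available via ``use_t``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .design import DesignSpec

__all__ = ["OLSFit", "fit_ols", "predict_ols", "backward_eliminate"]

# Predicted EQ-5D indices may be clipped to the attainable index range.
CLIP_RANGE = (-0.171, 1.0)


@dataclass
class OLSFit:
    """A fitted least-squares mapping with cluster-robust covariance."""

    labels: list[str]
    beta: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    r_squared: float
    n: int
    n_clusters: int
    spec: DesignSpec | None = None
    use_t: bool = False
    trace: list[dict] = field(default_factory=list)
    x_mean: np.ndarray | None = None
    y_mean: float | None = None

    @property
    def tvalues(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def pvalues(self) -> np.ndarray:
        z = np.abs(self.tvalues)
        if self.use_t:
            return 2 * stats.t.sf(z, df=max(self.n_clusters - 1, 1))
        return 2 * stats.norm.sf(z)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "r_squared": self.r_squared,
            "n": self.n,
            "n_clusters": self.n_clusters,
            "spec": self.spec.to_dict() if self.spec is not None else None,
            "trace": self.trace,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, data: dict) -> "OLSFit":
        spec = DesignSpec.from_dict(data["spec"]) if data.get("spec") else None
        beta = np.asarray(data["beta"], dtype=float)
        return cls(
            labels=list(data["labels"]),
            beta=beta,
            vcov=np.asarray(data["vcov"], dtype=float),
            se=np.asarray(data["se"], dtype=float),
            r_squared=float(data["r_squared"]),
            n=int(data["n"]),
            n_clusters=int(data["n_clusters"]),
            spec=spec,
            trace=list(data.get("trace", [])),
        )

    def summary(self) -> str:
        """Coefficient table (term, beta, robust SE, p) in fixed-width text."""
        lines = [f"{'term':<12}{'beta':>12}{'se':>12}{'p':>12}"]
        for lab, b, s, p in zip(self.labels, self.beta, self.se, self.pvalues):
            lines.append(f"{lab:<12}{b:>12.4f}{s:>12.4f}{p:>12.4g}")
        lines.append(f"n={self.n}  clusters={self.n_clusters}  R^2={self.r_squared:.4f}")
        return "\n".join(lines)


def _check_rank(X: np.ndarray, labels: Sequence[str]) -> None:
    n, k = X.shape
    if n < k:
        raise ValueError(f"more design columns ({k}) than observations ({n})")
    # tiny |R_ii| in the QR factor flags dependent columns
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if (diag < tol).any() or np.linalg.matrix_rank(X) < k:
        # identify offending columns by regressing each on the others
        bad = []
        for j in range(k):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(labels[j] if labels else str(j))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray | Sequence | None = None,
    labels: Sequence[str] | None = None,
    spec: DesignSpec | None = None,
    use_t: bool = False,
) -> OLSFit:
    """Least squares with a CR1 cluster-robust sandwich covariance.

    ``clusters`` may be None (every observation its own cluster, giving the
    HC1 estimator) or a label per row. Fewer than two distinct clusters
    triggers a warning and the heteroskedasticity-robust fallback.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has length {y.shape[0]}, X has {n} rows")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in design matrix or response")
    labels = list(labels) if labels is not None else [f"x{j}" for j in range(k)]
    _check_rank(X, labels)

    if clusters is not None:
        clusters = np.asarray(clusters)
        if clusters.shape[0] != n:
            raise ValueError("cluster vector length does not match data")
        if len(np.unique(clusters)) < 2:
            warnings.warn(
                "fewer than 2 clusters; falling back to heteroskedasticity-robust "
                "(singleton-cluster) variance",
                stacklevel=2,
            )
            clusters = None

    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    bread = np.linalg.inv(xtx)

    if clusters is None:
        g = n
        xe = X * resid[:, None]
        meat = xe.T @ xe
    else:
        uniq = np.unique(clusters)
        g = len(uniq)
        meat = np.zeros((k, k))
        for lab in uniq:
            idx = clusters == lab
            s = X[idx].T @ resid[idx]
            meat += np.outer(s, s)

    correction = (g / (g - 1)) * ((n - 1) / (n - k)) if g > 1 else 1.0
    vcov = correction * bread @ meat @ bread
    vcov = (vcov + vcov.T) / 2
    se = np.sqrt(np.diag(vcov))

    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0

    return OLSFit(
        labels=labels,
        beta=beta,
        vcov=vcov,
        se=se,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n=n,
        n_clusters=g if clusters is not None else n,
        spec=spec,
        use_t=use_t,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
    )


def predict_ols(
    fit: OLSFit,
    X_new: np.ndarray,
    labels: Sequence[str] | None = None,
    clip: bool = False,
) -> np.ndarray:
    """Linear predictions X·beta; unclipped by default (the index may be
    over-predicted above 1), optionally clipped to the attainable range."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != len(fit.beta):
        raise ValueError(
            f"design has {X_new.shape[1]} columns but the fit expects {len(fit.beta)} "
            f"({fit.labels})"
        )
    if labels is not None and list(labels) != list(fit.labels):
        raise ValueError(f"column labels {list(labels)} do not match fit labels {fit.labels}")
    pred = X_new @ fit.beta
    if clip:
        pred = np.clip(pred, CLIP_RANGE[0], CLIP_RANGE[1])
    return pred


def backward_eliminate(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray | None = None,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    spec: DesignSpec | None = None,
    use_t: bool = False,
) -> OLSFit:
    """Backward elimination at significance level ``alpha`` (default 0.05).

    Refits repeatedly, each time removing the single non-intercept term with
    the largest robust-Wald p-value, while any such p-value is >= alpha.
    Ties are broken by removing the later column in design order. The
    intercept is never removed. The elimination history is recorded on the
    returned fit's ``trace``.
    """
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    labels = list(labels) if labels is not None else [f"x{j}" for j in range(k)]
    keep = list(range(k))
    cur_spec = spec
    trace: list[dict] = []

    while True:
        fit = fit_ols(X[:, keep], y, clusters, [labels[j] for j in keep],
                      spec=cur_spec, use_t=use_t)
        pvals = fit.pvalues
        # candidates: every term except the intercept column (label 'const')
        cand = [i for i, lab in enumerate(fit.labels) if lab != "const"]
        if not cand:
            break
        worst = max(cand, key=lambda i: (pvals[i], i))
        if pvals[worst] < alpha:
            break
        dropped = fit.labels[worst]
        trace.append({"dropped": dropped, "p_value": float(pvals[worst]),
                      "n_terms_before": len(keep)})
        keep.pop(worst)
        if cur_spec is not None:
            cur_spec = cur_spec.drop_terms([dropped])
        if len(keep) == 0:
            raise ValueError("backward elimination removed every column")

    fit.trace = trace
    return fit
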