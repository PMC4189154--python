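"""Per-dimension multinomial-logit response mapping with Monte-Carlo
level assignment.

Instead of regressing the utility index directly, the response-mapping
approach fits a 3-level multinomial logit (reference level 1) for each of
the five EQ-5D dimensions on the SF-36 design, yielding per-subject
probabilities (P1, P2, P3) for each dimension. A uniform draw u per subject
per dimension then assigns the level by the inverse-CDF rule

    level = 1  if u <= P1
            2  if P1 < u <= 1 - P3
            3  if u > 1 - P3

(boundaries inclusive exactly as written). The five assigned levels form a
health state, which the value set scores to a utility; predictions therefore
always lie inside the attainable index range. Dimensions are modelled
independently — the joint state distribution is the product of the five
marginals.

Fitting goes through statsmodels' ``MNLogit`` (Newton), with two fallbacks:
a dimension observed at fewer than three levels collapses to a binary logit,
and suspected separation triggers a ridge-penalized refit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .design import DesignSpec
from .valueset import DIMENSIONS, EQ5DState, ValueSet, korea_tariff

__all__ = [
    "MNLFit",
    "fit_mnl_dimension",
    "assign_level",
    "simulate_states",
    "predict_mnl_utility",
]


@dataclass
class MNLFit:
    """A fitted 3-level multinomial logit for one EQ-5D dimension.

    ``coef`` holds one coefficient vector per non-reference level (keys 2
    and 3; a collapsed binary fit carries only the observed contrast).
    """

    dimension: str
    labels: list[str]
    coef: dict[int, np.ndarray]
    se: dict[int, np.ndarray]
    levels_present: tuple[int, ...]
    pseudo_r2: dict[str, float]
    llf: float
    llnull: float
    ridge: float = 0.0
    spec: DesignSpec | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) matrix of level probabilities; rows sum to 1."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.labels):
            raise ValueError(
                f"design has {X.shape[1]} columns but the {self.dimension} fit "
                f"expects {len(self.labels)} ({self.labels})"
            )
        # reference = lowest observed level; absent levels get probability 0
        eta = np.full((X.shape[0], 3), -np.inf)
        eta[:, self.levels_present[0] - 1] = 0.0
        for lev, b in self.coef.items():
            eta[:, lev - 1] = X @ b
        m = eta.max(axis=1, keepdims=True)
        ex = np.exp(eta - m)
        return ex / ex.sum(axis=1, keepdims=True)

    def to_dict(self) -> dict:
        return {
            "dimension": self.dimension,
            "labels": self.labels,
            "coef": {str(k): v.tolist() for k, v in self.coef.items()},
            "se": {str(k): v.tolist() for k, v in self.se.items()},
            "levels_present": list(self.levels_present),
            "pseudo_r2": self.pseudo_r2,
            "llf": self.llf,
            "llnull": self.llnull,
            "ridge": self.ridge,
        }


def _mcfadden_family(llf: float, llnull: float, n: int) -> dict[str, float]:
    out = {"mcfadden": 1.0 - llf / llnull if llnull != 0 else 0.0}
    cs = 1.0 - np.exp((2.0 / n) * (llnull - llf))
    out["cox_snell"] = float(cs)
    denom = 1.0 - np.exp((2.0 / n) * llnull)
    out["nagelkerke"] = float(cs / denom) if denom != 0 else float("nan")
    return out


def _ridge_mnl(X: np.ndarray, y01: np.ndarray, n_alt: int, ridge: float) -> np.ndarray:
    """Penalized multinomial MLE via BFGS; y01 is an (n, n_alt+1) indicator."""
    n, k = X.shape

    def negll(flat: np.ndarray) -> float:
        B = flat.reshape(k, n_alt)
        eta = np.column_stack([np.zeros(n), X @ B])
        m = eta.max(axis=1, keepdims=True)
        lse = m.ravel() + np.log(np.exp(eta - m).sum(axis=1))
        ll = float((y01 * eta).sum() - lse.sum())
        return -ll + ridge * float((flat**2).sum())

    res = optimize.minimize(negll, np.zeros(k * n_alt), method="BFGS",
                            options={"maxiter": 500})
    return res.x.reshape(k, n_alt)


def fit_mnl_dimension(
    X: np.ndarray,
    levels: np.ndarray,
    labels: Sequence[str] | None = None,
    dimension: str = "",
    spec: DesignSpec | None = None,
) -> MNLFit:
    """Fit the 3-level multinomial logit for one dimension.

    ``levels`` are the observed responses in {1, 2, 3}; level 1 is the
    reference. A level absent from the data collapses the model to a binary
    logit over the two observed levels (with a warning); separation falls
    back to a ridge-penalized fit.
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    levels = np.asarray(levels)
    if not np.isin(levels, [1, 2, 3]).all():
        raise ValueError("levels must be in {1, 2, 3}")
    labels = list(labels) if labels is not None else [f"x{j}" for j in range(X.shape[1])]
    present = tuple(int(v) for v in np.unique(levels))
    if len(present) < 2:
        raise ValueError(f"dimension {dimension or '?'}: only one level observed; nothing to fit")
    if len(present) == 2:
        warnings.warn(
            f"dimension {dimension or '?'}: level "
            f"{(set((1, 2, 3)) - set(present)).pop()} absent; collapsing to binary logit",
            stacklevel=2,
        )

    # map observed levels to 0..m-1 with the lowest level as reference
    codes = np.searchsorted(present, levels)
    n_alt = len(present) - 1

    ridge_used = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, X)
        try:
            res = model.fit(method="newton", maxiter=200, disp=False)
            params = np.asarray(res.params)  # (k, n_alt)
            bse = np.asarray(res.bse)
            llf, llnull = float(res.llf), float(res.llnull)
            score = model.score(res.params.ravel(order="F") if params.ndim > 1 else res.params)
            grad_norm = float(np.max(np.abs(score)))
            separated = not np.isfinite(params).all() or np.abs(params).max() > 30
        except Exception:
            separated, grad_norm = True, np.inf
            params = bse = None
            llf = llnull = np.nan

    if separated or grad_norm > 1e-6:
        if params is None or separated:
            warnings.warn(
                f"dimension {dimension or '?'}: suspected separation; "
                "refitting with a ridge penalty",
                stacklevel=2,
            )
            ridge_used = 1e-4
            y01 = np.zeros((len(codes), n_alt + 1))
            y01[np.arange(len(codes)), codes] = 1.0
            params = _ridge_mnl(X, y01, n_alt, ridge_used)
            bse = np.full_like(params, np.nan)
            # penalized log-likelihoods for the pseudo-R2 family
            eta = np.column_stack([np.zeros(len(codes)), X @ params])
            m = eta.max(axis=1, keepdims=True)
            lse = m.ravel() + np.log(np.exp(eta - m).sum(axis=1))
            llf = float((y01 * eta).sum() - lse.sum())
            pbar = y01.mean(axis=0)
            llnull = float(len(codes) * np.sum(pbar * np.log(np.clip(pbar, 1e-300, None))))

    coef = {present[j + 1]: np.asarray(params)[:, j].astype(float) for j in range(n_alt)}
    se = {present[j + 1]: np.asarray(bse)[:, j].astype(float) for j in range(n_alt)}
    n = len(levels)
    return MNLFit(
        dimension=dimension,
        labels=labels,
        coef=coef,
        se=se,
        levels_present=present,
        pseudo_r2=_mcfadden_family(llf, llnull, n),
        llf=llf,
        llnull=llnull,
        ridge=ridge_used,
        spec=spec,
    )


def assign_level(p1, p3, u):
    """Inverse-CDF level assignment from (P1, P3) and a uniform draw.

    level 1 iff u <= P1; level 2 iff P1 < u <= 1 - P3; level 3 iff
    u > 1 - P3. Inputs may be scalars or equal-shaped arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    u = np.asarray(u, dtype=float)
    tol = 1e-12
    if (p1 < -tol).any() or (p3 < -tol).any() or (p1 + p3 > 1 + tol).any():
        raise ValueError("(P1, P3) must lie in the probability simplex")
    if (u < 0).any() or (u > 1).any():
        raise ValueError("uniform draw u must lie in [0, 1]")
    level = np.full(np.broadcast(p1, p3, u).shape, 2, dtype=int)
    level = np.where(u <= p1, 1, level)
    level = np.where(u > 1.0 - p3, 3, level)
    if level.ndim == 0:
        return int(level)
    return level


def _five_fits(fits) -> list[MNLFit]:
    if isinstance(fits, Mapping):
        missing = [d for d in DIMENSIONS if d not in fits]
        if missing:
            raise ValueError(f"missing fitted dimensions: {missing}")
        return [fits[d] for d in DIMENSIONS]
    fits = list(fits)
    if len(fits) != 5:
        raise ValueError(f"need one fit per EQ-5D dimension (5), got {len(fits)}")
    return fits


def simulate_states(
    fits,
    X_new: np.ndarray,
    seed: int,
    n_draws: int = 1,
) -> np.ndarray:
    """Draw EQ-5D states: one uniform per subject per dimension per draw.

    Returns an integer level array of shape (n_draws, n_subjects, 5). The
    seed fully determines the output.
    """
    fits = _five_fits(fits)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    n = X_new.shape[0]
    probs = [f.predict_proba(X_new) for f in fits]  # each (n, 3)
    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, n, 5), dtype=int)
    for r in range(n_draws):
        u = rng.random((n, 5))
        for j in range(5):
            out[r, :, j] = assign_level(probs[j][:, 0], probs[j][:, 2], u[:, j])
    return out


def predict_mnl_utility(
    fits,
    X_new: np.ndarray,
    tariff: ValueSet | None = None,
    seed: int = 0,
    n_draws: int = 1,
    return_states: bool = False,
):
    """Score simulated states to utilities.

    Returns the per-subject mean utility over draws (for the paper-style
    single simulation, ``n_draws=1``, this is just the drawn utility).
    With ``return_states=True`` also returns the (n_draws, n, 5) level
    array and the per-draw utility matrix.
    """
    if tariff is None:
        tariff = korea_tariff()
    states = simulate_states(fits, X_new, seed=seed, n_draws=n_draws)
    n_draws_, n, _ = states.shape
    # score via a 243-entry lookup keyed on the level triple-base encoding
    lut = {}
    util = np.empty((n_draws_, n))
    for r in range(n_draws_):
        for i in range(n):
            key = tuple(states[r, i])
            if key not in lut:
                lut[key] = tariff.utility(EQ5DState(*key))
            util[r, i] = lut[key]
    mean_util = util.mean(axis=0)
    if return_states:
        return mean_util, states, util
    return mean_util


def expected_utility(fits, X_new: np.ndarray, tariff: ValueSet | None = None) -> np.ndarray:
    """Exact expectation of the simulated utility over all 243 states.

    E[U] = Σ_state Π_j P_{level_j} · U(state), using the independence of
    dimensions. Useful as the analytic limit of the Monte-Carlo assignment.
    """
    from itertools import product

    if tariff is None:
        tariff = korea_tariff()
    fits = _five_fits(fits)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    probs = [f.predict_proba(X_new) for f in fits]
    n = X_new.shape[0]
    out = np.zeros(n)
    for levels in product((1, 2, 3), repeat=5):
        w = np.ones(n)
        for j, lev in enumerate(levels):
            w = w * probs[j][:, lev - 1]
        out += w * tariff.utility(EQ5DState(*levels))
    return out
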