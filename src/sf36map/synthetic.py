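"""Synthetic SF-36 / EQ-5D-3L cohorts with known ground truth.

A single latent health factor h drives both instruments, which is the
premise of any SF-36 → EQ-5D mapping: the two questionnaires measure
overlapping constructs. Per subject,

    h = latent_mean + cluster effect N(0, sd_between²) + N(0, sd_within²)

* SF-36 domain scores (and PCS/MCS) are linear in h plus Gaussian noise,
  truncated to [0, 100] — truncation, not resampling, so the generator shows
  the mild instrument ceilings real SF-36 data have;
* each EQ-5D dimension level comes from a proportional-odds (ordered-logit)
  link: P(level ≤ k | h) = sigmoid(c_k + s·h) with thresholds c_1 < c_2,
  realized through one uniform draw per subject per dimension;
* the EQ-5D index is scored from the generated levels through the tariff,
  so levels and index are consistent by construction.

Presets emulate the severity spectrum of the Korean crosswalk cohorts —
a healthy general population (index mean ≈ 0.945, ceiling ≈ 65%), diabetic
outpatients (≈ 0.914, ≈ 53%), community stroke survivors (≈ 0.513, ≈ 3%
ceiling), and their mixture in the original 448 : 770 : 442 proportions.
Preset threshold/mean values were calibrated once, by simulation at large n,
against those cohort summaries.

An optional ``true_mapping`` adds a response column generated from a known
linear model of the scores, for parameter-recovery experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DOMAIN_SCORES
from .valueset import DIMENSIONS, EQ5DState, ValueSet, korea_tariff

__all__ = ["CohortParams", "preset", "generate_cohort", "PRESET_NAMES"]

PRESET_NAMES = ("general", "diabetes", "stroke", "mixed")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


@dataclass(frozen=True)
class CohortParams:
    """Everything needed to generate one cohort deterministically."""

    name: str
    n: int
    n_clusters: int
    seed: int
    latent_mean: float = 0.0
    latent_sd_between: float = 0.3
    latent_sd_within: float = 1.0
    #: per-domain (and PCS/MCS) linear link: score = intercept + loading·h + noise
    domain_loadings: Mapping[str, float] = field(default_factory=dict)
    domain_intercepts: Mapping[str, float] = field(default_factory=dict)
    domain_noise_sd: Mapping[str, float] = field(default_factory=dict)
    #: ordered-logit link per dimension: P(level <= k | h) = sigmoid(c_k + s·h)
    dimension_thresholds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    dimension_slopes: Mapping[str, float] = field(default_factory=dict)
    age_mean: float = 55.0
    age_sd: float = 14.0
    female_frac: float = 0.45
    #: optional known linear model adding a Y_TRUE response column:
    #: {"intercept": b0, "coefs": {col: b}, "noise_sd": s, "divisor": d}
    true_mapping: Mapping | None = None
    #: set for the "mixed" preset: sub-cohorts and their mixing weights
    components: tuple[tuple["CohortParams", float], ...] | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if self.components is not None:
            return
        if self.n_clusters < 1:
            raise ValueError(f"n_clusters must be >= 1, got {self.n_clusters}")
        if self.latent_sd_between < 0 or self.latent_sd_within <= 0:
            raise ValueError("latent_sd_between must be >= 0 and latent_sd_within > 0")
        for dim, (c1, c2) in self.dimension_thresholds.items():
            if not c1 < c2:
                raise ValueError(
                    f"dimension_thresholds[{dim!r}] must be strictly increasing, got {(c1, c2)}"
                )
        for col, sd in self.domain_noise_sd.items():
            if sd < 0:
                raise ValueError(f"domain_noise_sd[{col!r}] must be >= 0")

    def to_json(self, path: str | Path) -> None:
        def enc(obj):
            if isinstance(obj, CohortParams):
                d = {k: v for k, v in obj.__dict__.items() if k != "components"}
                if obj.components:
                    d["components"] = [[enc(p), w] for p, w in obj.components]
                return d
            return obj

        Path(path).write_text(json.dumps(enc(self), default=lambda o: dict(o), indent=2))


# ---------------------------------------------------------------------------
# Preset parameters.
#
# Domain links are anchored at the published cohort means of the general
# (healthiest) and stroke (most impaired) cohorts, placed at their calibrated
# latent means; thresholds and latent means were tuned by simulation so each
# preset's index mean and ceiling fraction land near its target.
# ---------------------------------------------------------------------------

# (general mean, stroke mean) anchors for each 0-100 score
_DOMAIN_ANCHORS: dict[str, tuple[float, float]] = {
    "PF": (86.6, 25.0),
    "RP": (89.0, 29.8),
    "BP": (84.4, 50.8),
    "GH": (66.3, 29.2),
    "VT": (54.1, 23.3),
    "SF": (89.0, 38.4),
    "RE": (89.8, 40.2),
    "MH": (76.9, 44.5),
    "PCS": (52.2, 32.3),
    "MCS": (49.9, 31.9),
}

_DOMAIN_NOISE_SD: dict[str, float] = {
    "PF": 12.0, "RP": 14.0, "BP": 14.0, "GH": 12.0, "VT": 12.0,
    "SF": 12.0, "RE": 14.0, "MH": 12.0, "PCS": 5.0, "MCS": 7.0,
}

# calibrated latent means (filled by the one-off calibration run)
_LATENT_MEANS = {"general": 0.97, "diabetes": 0.60, "stroke": -1.40}

# calibrated shared ordered-logit link
_THRESHOLDS: dict[str, tuple[float, float]] = {
    "MO": (1.45, 4.6),
    "SC": (2.35, 4.9),
    "UA": (1.75, 4.4),
    "PD": (0.95, 3.9),
    "AD": (1.35, 4.1),
}
_SLOPES: dict[str, float] = {"MO": 1.9, "SC": 1.9, "UA": 1.9, "PD": 1.6, "AD": 1.3}

_AGE = {"general": (44.5, 15.5), "diabetes": (57.6, 11.9), "stroke": (68.3, 8.2)}
_FEMALE = {"general": 0.502, "diabetes": 0.444, "stroke": 0.398}
_CLUSTERS = {"general": 25, "diabetes": 3, "stroke": 4}
_MIX_WEIGHTS = {"general": 448, "diabetes": 770, "stroke": 442}  # source cohort sizes


def _domain_links() -> tuple[dict, dict]:
    mg, ms = _LATENT_MEANS["general"], _LATENT_MEANS["stroke"]
    loadings, intercepts = {}, {}
    for col, (g, s) in _DOMAIN_ANCHORS.items():
        slope = (g - s) / (mg - ms)
        loadings[col] = slope
        intercepts[col] = g - slope * mg
    return loadings, intercepts


def preset(name: str, n: int | None = None, seed: int = 0) -> CohortParams:
    """Parameters for a named cohort preset.

    ``n`` defaults to a survey-sized cohort (2000; the mixed preset splits it
    in the source 448 : 770 : 442 proportions).
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available presets: {list(PRESET_NAMES)}")
    n = int(n) if n is not None else 2000
    if name == "mixed":
        total = sum(_MIX_WEIGHTS.values())
        comps = tuple(
            (preset(sub, n=max(1, round(n * w / total)), seed=seed + 17 * (i + 1)), w / total)
            for i, (sub, w) in enumerate(_MIX_WEIGHTS.items())
        )
        return CohortParams(name="mixed", n=n, n_clusters=sum(_CLUSTERS.values()),
                            seed=seed, components=comps)
    loadings, intercepts = _domain_links()
    return CohortParams(
        name=name,
        n=n,
        n_clusters=_CLUSTERS[name],
        seed=seed,
        latent_mean=_LATENT_MEANS[name],
        domain_loadings=loadings,
        domain_intercepts=intercepts,
        domain_noise_sd=dict(_DOMAIN_NOISE_SD),
        dimension_thresholds=dict(_THRESHOLDS),
        dimension_slopes=dict(_SLOPES),
        age_mean=_AGE[name][0],
        age_sd=_AGE[name][1],
        female_frac=_FEMALE[name],
    )


def generate_cohort(
    params: CohortParams,
    tariff: ValueSet | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate one cohort; deterministic given ``params.seed``.

    Returns the subject table (scores, levels, state string, tariff-scored
    index, demographics, cluster id, latent health) and a ground-truth
    record (the parameters, and the true coefficients when ``true_mapping``
    is set).
    """
    if tariff is None:
        tariff = korea_tariff()

    if params.components is not None:
        frames, truths, offset = [], {}, 0
        for sub, _w in params.components:
            df, gt = generate_cohort(sub, tariff)
            df = df.copy()
            df["CLUSTER"] = df["CLUSTER"] + offset
            offset = int(df["CLUSTER"].max()) + 1
            df["COHORT"] = sub.name
            frames.append(df)
            truths[sub.name] = gt
        out = pd.concat(frames, ignore_index=True)
        return out, {"name": params.name, "seed": params.seed, "components": truths}

    rng = np.random.default_rng(params.seed)
    n, g = params.n, params.n_clusters
    cluster = rng.integers(0, g, size=n)
    cluster_eff = rng.normal(0.0, params.latent_sd_between, size=g)
    h = params.latent_mean + cluster_eff[cluster] + rng.normal(0.0, params.latent_sd_within, size=n)

    data: dict[str, np.ndarray] = {}
    for col in list(DOMAIN_SCORES) + ["PCS", "MCS"]:
        if col not in params.domain_loadings:
            continue
        raw = (
            params.domain_intercepts.get(col, 0.0)
            + params.domain_loadings[col] * h
            + rng.normal(0.0, params.domain_noise_sd.get(col, 0.0), size=n)
        )
        data[col] = np.clip(raw, 0.0, 100.0)

    levels = np.empty((n, 5), dtype=int)
    for j, dim in enumerate(DIMENSIONS):
        c1, c2 = params.dimension_thresholds[dim]
        s = params.dimension_slopes[dim]
        u = rng.random(n)
        p_le1 = _sigmoid(c1 + s * h)
        p_le2 = _sigmoid(c2 + s * h)
        levels[:, j] = 1 + (u > p_le1).astype(int) + (u > p_le2).astype(int)

    index = np.array([tariff.utility(EQ5DState(*row)) for row in levels])

    df = pd.DataFrame(data)
    for j, dim in enumerate(DIMENSIONS):
        df[dim] = levels[:, j]
    df["STATE"] = ["".join(str(v) for v in row) for row in levels]
    df["EQ5D"] = index
    df["AGE"] = np.clip(rng.normal(params.age_mean, params.age_sd, size=n), 18, 100).round(0)
    df["SEX"] = np.where(rng.random(n) < params.female_frac, "F", "M")
    df["CLUSTER"] = cluster
    df["LATENT"] = h

    truth: dict = {"name": params.name, "seed": params.seed,
                   "latent_mean": params.latent_mean}
    if params.true_mapping is not None:
        tm = params.true_mapping
        div = float(tm.get("divisor", 1.0))
        y = np.full(n, float(tm["intercept"]))
        for col, b in tm["coefs"].items():
            y = y + float(b) * df[col].to_numpy() / div
        y = y + rng.normal(0.0, float(tm.get("noise_sd", 0.0)), size=n)
        df["Y_TRUE"] = y
        truth["true_mapping"] = {
            "intercept": float(tm["intercept"]),
            "coefs": {k: float(v) for k, v in tm["coefs"].items()},
            "noise_sd": float(tm.get("noise_sd", 0.0)),
            "divisor": div,
        }
    return df, truth
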