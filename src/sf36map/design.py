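"""SF-36 profile validation and design-matrix construction.

The SF-36 yields eight 0–100 domain scores — physical functioning (PF),
role-physical (RP), bodily pain (BP), general health (GH), vitality (VT),
social functioning (SF), role-emotional (RE), mental health (MH) — and two
norm-based summaries (PCS, MCS). A :class:`DesignSpec` names which of these
(plus squared terms, pairwise interactions and demographic covariates) enter
a mapping regression, and :func:`build_design_matrix` turns validated
profiles into the numeric matrix the estimators consume.

Six specifications are packaged, mirroring the standard crosswalk model
ladder:

m1  all eight domain scores (main effects)
m2  eight domain scores, backward elimination
m3  eight domain scores + their squared terms, backward elimination
m4  m3 + demographic covariates (age, sex, education, marital status),
    backward elimination
m5  PCS + MCS
m6  PCS, MCS, PCS², MCS², PCS×MCS

Score covariates are divided by ``scale_divisor`` (default 10) before any
squaring or interaction; the default keeps squared-term coefficients on a
numerically comfortable scale and is exactly reversible (rescaling fitted
coefficients by powers of the divisor reproduces divisor-1 predictions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DOMAIN_SCORES",
    "SUMMARY_SCORES",
    "DesignSpec",
    "model_spec",
    "validate_profiles",
    "build_design_matrix",
]

DOMAIN_SCORES: tuple[str, ...] = ("PF", "RP", "BP", "GH", "VT", "SF", "RE", "MH")
SUMMARY_SCORES: tuple[str, ...] = ("PCS", "MCS")
_SCORE_COLS = DOMAIN_SCORES + SUMMARY_SCORES
_DEMOGRAPHICS = ("AGE", "SEX", "EDU", "MARITAL")


@dataclass(frozen=True)
class DesignSpec:
    """A mapping-model design: which covariates, and how they are transformed.

    Parameters
    ----------
    model_id:
        Identifier (``m1``–``m6`` for the packaged ladder, or any custom id).
    main:
        Score covariates entering linearly (domain and/or summary scores).
    squared:
        Scores whose squares are added; each must also appear in ``main``.
    interactions:
        Pairs of scores whose product is added; both members must be in ``main``.
    demographics:
        Demographic covariates: ``AGE`` numeric; ``SEX``/``EDU``/``MARITAL``
        dummy-coded with the first observed category as reference.
    scale_divisor:
        Positive divisor applied to every score covariate before term
        construction (demographics are never scaled).
    backward:
        Whether the packaged workflow applies p<0.05 backward elimination.
    """

    model_id: str
    main: tuple[str, ...]
    squared: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    demographics: tuple[str, ...] = ()
    scale_divisor: float = 10.0
    backward: bool = False
    #: True for specs produced by term elimination, where a squared term may
    #: legitimately outlive its main effect (elimination is non-hierarchical).
    derived: bool = False

    def __post_init__(self) -> None:
        if self.scale_divisor <= 0:
            raise ValueError(f"scale_divisor must be positive, got {self.scale_divisor}")
        for name in self.main + self.squared:
            if name not in _SCORE_COLS:
                raise ValueError(f"unknown score covariate {name!r}")
        for a, b in self.interactions:
            if a not in _SCORE_COLS or b not in _SCORE_COLS:
                raise ValueError(f"interaction {a}x{b} references an unknown covariate")
        if not self.derived:
            for name in self.squared:
                if name not in self.main:
                    raise ValueError(f"squared term {name!r} references a predictor not in main")
            for a, b in self.interactions:
                if a not in self.main or b not in self.main:
                    raise ValueError(f"interaction {a}x{b} references a predictor not in main")
        for name in self.demographics:
            if name not in _DEMOGRAPHICS:
                raise ValueError(f"unknown demographic covariate {name!r}")

    @property
    def uses_summary(self) -> bool:
        return any(c in SUMMARY_SCORES for c in self.main)

    def term_labels(self) -> list[str]:
        """Score-term labels in design order (demographic dummies are data-dependent)."""
        labels = ["const"]
        labels += list(self.main)
        labels += [f"{c}^2" for c in self.squared]
        labels += [f"{a}*{b}" for a, b in self.interactions]
        return labels

    def drop_terms(self, names: Sequence[str]) -> "DesignSpec":
        """A copy of this spec with the named (non-intercept) term labels removed.

        Elimination is non-hierarchical: dropping a main effect does not drop
        its squared term, and vice versa.
        """
        names = set(names)
        main = tuple(c for c in self.main if c not in names)
        squared = tuple(c for c in self.squared if f"{c}^2" not in names)
        interactions = tuple(p for p in self.interactions if f"{p[0]}*{p[1]}" not in names)
        demographics = tuple(d for d in self.demographics if d not in names)
        return replace(self, main=main, squared=squared, interactions=interactions,
                       demographics=demographics, derived=True)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "main": list(self.main),
            "squared": list(self.squared),
            "interactions": [list(p) for p in self.interactions],
            "demographics": list(self.demographics),
            "scale_divisor": self.scale_divisor,
            "backward": self.backward,
            "derived": self.derived,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DesignSpec":
        return cls(
            model_id=data["model_id"],
            main=tuple(data.get("main", ())),
            squared=tuple(data.get("squared", ())),
            interactions=tuple(tuple(p) for p in data.get("interactions", ())),
            demographics=tuple(data.get("demographics", ())),
            scale_divisor=float(data.get("scale_divisor", 10.0)),
            backward=bool(data.get("backward", False)),
            derived=bool(data.get("derived", False)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignSpec":
        import yaml

        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text))


_PACKAGED_SPECS: dict[str, DesignSpec] = {
    "m1": DesignSpec("m1", main=DOMAIN_SCORES),
    "m2": DesignSpec("m2", main=DOMAIN_SCORES, backward=True),
    "m3": DesignSpec("m3", main=DOMAIN_SCORES, squared=DOMAIN_SCORES, backward=True),
    "m4": DesignSpec(
        "m4",
        main=DOMAIN_SCORES,
        squared=DOMAIN_SCORES,
        demographics=_DEMOGRAPHICS,
        backward=True,
    ),
    "m5": DesignSpec("m5", main=SUMMARY_SCORES),
    "m6": DesignSpec(
        "m6",
        main=SUMMARY_SCORES,
        squared=SUMMARY_SCORES,
        interactions=(("PCS", "MCS"),),
    ),
}


def model_spec(model_id: str) -> DesignSpec:
    """Return a packaged specification (``m1`` … ``m6``)."""
    key = model_id.lower()
    if key not in _PACKAGED_SPECS:
        raise KeyError(f"unknown model id {model_id!r}; packaged specs: {sorted(_PACKAGED_SPECS)}")
    return _PACKAGED_SPECS[key]


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        up = col.strip().upper()
        if up in _SCORE_COLS or up in _DEMOGRAPHICS or up in ("CLUSTER", "EQ5D"):
            mapping[col] = up
    return df.rename(columns=mapping)


def validate_profiles(
    records: pd.DataFrame,
    require: Sequence[str] = DOMAIN_SCORES,
) -> tuple[pd.DataFrame, list[str]]:
    """Validate SF-36 profile rows; reject (never impute) bad rows.

    A row is rejected when any required score is missing or outside [0, 100].
    Returns the accepted rows (original index preserved) and a list of
    human-readable issues, one per rejected row.

    Raises :class:`ValueError` on empty input or when every row is invalid.
    """
    if records is None or len(records) == 0:
        raise ValueError("no profile records supplied")
    df = _normalize_columns(records)
    missing_cols = [c for c in require if c not in df.columns]
    if missing_cols:
        raise ValueError(f"input is missing required columns: {missing_cols}")

    issues: list[str] = []
    bad = pd.Series(False, index=df.index)
    for col in require:
        vals = pd.to_numeric(df[col], errors="coerce")
        df[col] = vals
        isna = vals.isna()
        out = ~isna & ((vals < 0) | (vals > 100))
        for idx in df.index[isna]:
            issues.append(f"row {idx}: {col} missing or non-numeric")
        for idx in df.index[out]:
            issues.append(f"row {idx}: {col} out of [0,100] (value {vals[idx]:g})")
        bad |= isna | out
    accepted = df.loc[~bad].copy()
    if len(accepted) == 0:
        raise ValueError("all rows invalid:\n" + "\n".join(issues))
    return accepted, issues


def build_design_matrix(
    profiles: pd.DataFrame,
    spec: DesignSpec,
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    """Build the numeric design matrix for a specification.

    Columns are ordered ``[intercept, main effects, squared terms,
    interactions, demographics]``; score covariates are divided by
    ``spec.scale_divisor`` before any squaring or interaction. Returns the
    matrix, its column labels (which round-trip with fitted coefficient
    names) and the cluster vector when a CLUSTER column is present.
    """
    df = _normalize_columns(profiles)
    score_cols = set(spec.main) | set(spec.squared) | {c for p in spec.interactions for c in p}
    needed = score_cols | set(spec.demographics)
    absent = [c for c in sorted(needed) if c not in df.columns]
    if absent:
        raise ValueError(f"design spec {spec.model_id!r} needs columns absent from data: {absent}")

    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["const"]

    scaled: dict[str, np.ndarray] = {}
    for name in sorted(score_cols):
        vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"column {name} contains missing values; validate profiles first")
        scaled[name] = vals / spec.scale_divisor
    for name in spec.main:
        cols.append(scaled[name])
        labels.append(name)
    for name in spec.squared:
        cols.append(scaled[name] ** 2)
        labels.append(f"{name}^2")
    for a, b in spec.interactions:
        cols.append(scaled[a] * scaled[b])
        labels.append(f"{a}*{b}")
    for name in spec.demographics:
        if name == "AGE":
            age = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
            if np.isnan(age).any():
                raise ValueError("AGE contains missing values")
            cols.append(age)
            labels.append("AGE")
        else:
            cats = df[name].astype("category")
            levels = list(cats.cat.categories)
            for lev in levels[1:]:  # first category is the reference
                cols.append((cats == lev).to_numpy(dtype=float))
                labels.append(f"{name}[{lev}]")

    X = np.column_stack(cols)
    clusters = df["CLUSTER"].to_numpy() if "CLUSTER" in df.columns else None
    return X, labels, clusters
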