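"""Published OLS crosswalk coefficients, packaged as ready-to-use predictors.

The six fitted OLS mappings from the Korean SF-36 → EQ-5D-3L crosswalk
study are shipped verbatim (coefficients and standard errors as printed,
with non-significant terms flagged). They let a user convert SF-36 profiles
to approximate EQ-5D utilities without refitting.

**Scale caveat.** The source publication does not state the units its
covariates were in when the models were fitted (raw 0–100 scores, or scores
divided by 10 — a common convention that tames squared-term magnitudes).
Neither convention reproduces the publication's own predicted mean when the
models are evaluated at its reported covariate means: model m1 at the
derivation-set domain-score means yields ≈3.85 under ``raw`` and ≈0.40
under ``div10``, against a reported predicted mean of 0.816. The intended
units (or a misprint) cannot be determined from the publication alone, so
:func:`crosswalk` refuses to guess — the caller must pick a convention
explicitly and every result carries a :class:`CrosswalkCaveat`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, build_design_matrix

__all__ = ["PublishedCoefficients", "CrosswalkCaveat", "load_published", "crosswalk",
           "SCALE_CONVENTIONS"]

SCALE_CONVENTIONS = ("raw", "div10")

# printed term name -> design-matrix label
_TERM_TO_LABEL = {
    "Intercept": "const",
    "PF squared": "PF^2",
    "SF squared": "SF^2",
    "RE squared": "RE^2",
    "PCS x PCS": "PCS^2",
    "MCS x MCS": "MCS^2",
    "PCS x MCS": "PCS*MCS",
    "Age": "AGE",
}


@dataclass(frozen=True)
class PublishedCoefficients:
    """One published model: printed terms, coefficients and standard errors."""

    model_id: str
    terms: tuple[str, ...]
    beta: tuple[float, ...]
    se: tuple[float, ...]
    significant: tuple[bool, ...]
    source_doi: str
    source_table: str
    reported: dict

    @property
    def nonsignificant_terms(self) -> tuple[str, ...]:
        return tuple(t for t, s in zip(self.terms, self.significant) if not s)

    def design_spec(self, scale_divisor: float) -> DesignSpec:
        """The DesignSpec whose columns line up with these coefficients."""
        main, squared, inter, demo = [], [], [], []
        for term in self.terms:
            if term == "Intercept":
                continue
            label = _TERM_TO_LABEL.get(term, term)
            if label == "AGE":
                demo.append("AGE")
            elif label.endswith("^2"):
                squared.append(label[:-2])
            elif "*" in label:
                inter.append(tuple(label.split("*")))
            else:
                main.append(label)
        return DesignSpec(
            model_id=self.model_id,
            main=tuple(main),
            squared=tuple(squared),
            interactions=tuple(inter),
            demographics=tuple(demo),
            scale_divisor=scale_divisor,
            derived=True,
        )

    def beta_for_labels(self, labels: Sequence[str]) -> np.ndarray:
        by_label = {_TERM_TO_LABEL.get(t, t): b for t, b in zip(self.terms, self.beta)}
        missing = [lab for lab in labels if lab not in by_label]
        if missing:
            raise ValueError(f"model {self.model_id} has no coefficient for {missing}")
        return np.array([by_label[lab] for lab in labels], dtype=float)


@dataclass(frozen=True)
class CrosswalkCaveat:
    """Mandatory warning record attached to every published-model prediction."""

    model_id: str
    scale_convention: str
    message: str


def _load_raw() -> dict:
    with resources.files("sf36map.data").joinpath("table2_coefficients.json").open() as fh:
        return json.load(fh)


def load_published(model_id: str) -> PublishedCoefficients:
    """Load one packaged published model (``m1`` … ``m6``)."""
    data = _load_raw()
    key = model_id.lower()
    if key not in data["models"]:
        raise KeyError(f"unknown published model {model_id!r}; available: {sorted(data['models'])}")
    block = data["models"][key]
    return PublishedCoefficients(
        model_id=key,
        terms=tuple(t["term"] for t in block["terms"]),
        beta=tuple(float(t["beta"]) for t in block["terms"]),
        se=tuple(float(t["se"]) for t in block["terms"]),
        significant=tuple(bool(t["significant"]) for t in block["terms"]),
        source_doi=data["source_doi"],
        source_table=data["source_table"],
        reported=dict(block.get("reported", {})),
    )


def crosswalk(
    profiles: pd.DataFrame,
    model_id: str,
    scale_convention: str | None = None,
    clip: bool = False,
) -> tuple[np.ndarray, CrosswalkCaveat]:
    """Predict EQ-5D utilities from SF-36 profiles with a published model.

    ``scale_convention`` must be chosen explicitly: ``"raw"`` feeds the
    0–100 scores (and PCS/MCS) straight into the linear predictor;
    ``"div10"`` divides every score covariate by 10 before any squaring or
    interaction. There is no default — the source's units are unknown (see
    module docstring) — and every result is paired with a
    :class:`CrosswalkCaveat` restating the ambiguity.
    """
    if scale_convention is None:
        raise ValueError(
            "scale_convention is required ('raw' or 'div10'): the publication does "
            "not state its covariate units, so no silent default is offered"
        )
    if scale_convention not in SCALE_CONVENTIONS:
        raise ValueError(f"unknown scale_convention {scale_convention!r}; use one of {SCALE_CONVENTIONS}")

    pub = load_published(model_id)
    divisor = 1.0 if scale_convention == "raw" else 10.0
    spec = pub.design_spec(scale_divisor=divisor)
    X, labels, _ = build_design_matrix(profiles, spec)
    beta = pub.beta_for_labels(labels)
    pred = X @ beta
    if clip:
        pred = np.clip(pred, -0.171, 1.0)
    caveat = CrosswalkCaveat(
        model_id=pub.model_id,
        scale_convention=scale_convention,
        message=(
            f"published model {pub.model_id} evaluated under the '{scale_convention}' "
            "covariate convention; the source does not state its covariate units and "
            "neither 'raw' nor 'div10' reproduces its reported predicted mean (0.816) "
            "at its reported covariate means — interpret the utility scale with care"
        ),
    )
    return pred, caveat
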