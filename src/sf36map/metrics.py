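"""Validation battery for observed-vs-predicted EQ-5D indices.

MAE (mean absolute error), RMSE, the proportions of predictions whose
absolute error exceeds 0.05 and 0.1 (strict inequality; an error of exactly
0.05 does not count), and predicted-index summaries. For context, 0.05–0.1
brackets the minimal important difference usually quoted for the EQ-5D
index (≈0.074), so the exceedance rates read as "share of subjects whose
mapped utility is off by a clinically relevant amount".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ValidationReport", "validate", "performance_table"]


@dataclass(frozen=True)
class ValidationReport:
    """Performance of one mapping model on one dataset.

    ``ae_gt_05``/``ae_gt_10`` are percentages in [0, 100]. ``r2`` is filled
    only for linear fits; ``pseudo_r2_range`` only for response-mapping
    (multinomial) models — neither is improvised for the other families.
    """

    mae: float
    rmse: float
    ae_gt_05: float
    ae_gt_10: float
    pred_mean: float
    pred_sd: float
    pred_min: float
    pred_max: float
    n: int
    r2: float | None = None
    pseudo_r2_range: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.pseudo_r2_range is not None:
            d["pseudo_r2_range"] = list(self.pseudo_r2_range)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def validate(
    observed: np.ndarray,
    predicted: np.ndarray,
    r2: float | None = None,
    pseudo_r2_range: tuple[float, float] | None = None,
) -> ValidationReport:
    """Compare observed and predicted index vectors.

    MAE = mean |o − p|; RMSE = sqrt(mean (o − p)²); exceedance proportions
    use strict '>' at 0.05 and 0.1. Predicted-value summaries use the
    population SD convention (ddof=1 when n > 1).
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: observed has {observed.size}, predicted has {predicted.size}"
        )
    if observed.size == 0:
        raise ValueError("empty input")
    if not (np.isfinite(observed).all() and np.isfinite(predicted).all()):
        raise ValueError("non-finite values in observed or predicted")

    err = observed - predicted
    abs_err = np.abs(err)
    n = observed.size
    return ValidationReport(
        mae=float(abs_err.mean()),
        rmse=float(math.sqrt(np.mean(err**2))),
        ae_gt_05=float(100.0 * np.mean(abs_err > 0.05)),
        ae_gt_10=float(100.0 * np.mean(abs_err > 0.1)),
        pred_mean=float(predicted.mean()),
        pred_sd=float(predicted.std(ddof=1)) if n > 1 else 0.0,
        pred_min=float(predicted.min()),
        pred_max=float(predicted.max()),
        n=n,
        r2=r2,
        pseudo_r2_range=pseudo_r2_range,
    )


_ROWS = [
    ("MAE", lambda r: f"{r.mae:.3f}"),
    ("AE > 0.05 (%)", lambda r: f"{r.ae_gt_05:.1f}"),
    ("AE > 0.1 (%)", lambda r: f"{r.ae_gt_10:.1f}"),
    ("RMSE", lambda r: f"{r.rmse:.3f}"),
    ("Mean (SD)", lambda r: f"{r.pred_mean:.3f} ({r.pred_sd:.3f})"),
    ("Min/max", lambda r: f"{r.pred_min:.3f}/{r.pred_max:.3f}"),
    ("R^2", lambda r: "" if r.r2 is None else f"{r.r2:.4f}"),
    (
        "pseudo R^2",
        lambda r: ""
        if r.pseudo_r2_range is None
        else f"{r.pseudo_r2_range[0]:.3f}-{r.pseudo_r2_range[1]:.3f}",
    ),
]


def performance_table(reports: Mapping[str, ValidationReport]) -> pd.DataFrame:
    """Side-by-side comparison panel, one column per named model.

    Row layout follows the conventional crosswalk-performance presentation
    (MAE, exceedance rates, RMSE, predicted mean/SD and range). Column
    order follows the mapping's insertion order. ``to_csv`` of the result is
    byte-stable for fixed inputs.
    """
    if not reports:
        raise ValueError("no reports supplied")
    data = {name: [fmt(rep) for _, fmt in _ROWS] for name, rep in reports.items()}
    return pd.DataFrame(data, index=[label for label, _ in _ROWS])
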