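"""BrainAGE computation: raw gap, age-bias residualization, z-scores.

The brain age gap is predicted age minus chronological age (positive =
older-looking brain).  Because regression-to-the-mean makes raw gaps
correlate with chronological age, the shared variance is removed with an
ordinary least squares fit

    gap = intercept + alpha * chronological_age + residual

and the residual (the corrected gap) is converted to a z-score against the
healthy-control distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class BiasModel:
    """OLS age-bias model with its fit provenance.

    ``regressand`` records whether the fit was gap-on-age (default; the
    slope alpha is then the age bias of the gap) or the literal
    predicted-age-on-age variant.
    """

    intercept: float
    alpha: float
    fit_population: str = "controls"   # controls | training | pooled
    regressand: str = "gap"            # gap | predicted_age

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.alpha)):
            raise ValueError("bias model coefficients must be finite")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "BiasModel":
        return cls(**json.loads(payload))


@dataclass(frozen=True)
class ControlReference:
    """Mean/SD of corrected gaps in the control group (sample SD, n-1)."""

    mean_gap: float
    sd_gap: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("control reference needs at least 2 controls")
        if not self.sd_gap > 0:
            raise ValueError("control reference SD must be > 0")


@dataclass(frozen=True)
class BrainAgeResult:
    """Per-subject BrainAGE quantities."""

    predicted_age: float
    chronological_age: float
    raw_gap: float
    corrected_gap: float = np.nan
    z_score: float = np.nan


def raw_gap(predicted: float, chronological: float) -> float:
    """Brain age gap in years: predicted minus chronological age."""
    if not (np.isfinite(predicted) and np.isfinite(chronological)):
        raise ValueError("ages must be finite")
    return float(predicted - chronological)


def result_from_ages(predicted: float, chronological: float) -> BrainAgeResult:
    return BrainAgeResult(
        predicted_age=float(predicted),
        chronological_age=float(chronological),
        raw_gap=raw_gap(predicted, chronological),
    )


def fit_bias_model(
    gaps: Sequence[float],
    ages: Sequence[float],
    fit_population: str = "controls",
    regressand: str = "gap",
) -> BiasModel:
    """OLS of the gap (or predicted age) on chronological age.

    With ``regressand='predicted_age'`` the inputs in ``gaps`` are treated
    as predicted ages and the literal predicted-on-age regression is fitted;
    the returned model is still applied to gaps (the gap variant subtracts 1
    from the predicted-age slope, which is the algebraically identical
    correction).
    """
    y = np.asarray(gaps, dtype=np.float64)
    x = np.asarray(ages, dtype=np.float64)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need at least 3 (gap, age) pairs")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("constant ages: singular design")
    alpha, intercept = np.polyfit(x, y, 1)
    if regressand == "predicted_age":
        # predicted = intercept + alpha*age  <=>  gap = intercept + (alpha-1)*age
        alpha = alpha - 1.0
    elif regressand != "gap":
        raise ValueError("regressand must be 'gap' or 'predicted_age'")
    return BiasModel(
        intercept=float(intercept),
        alpha=float(alpha),
        fit_population=fit_population,
        regressand=regressand,
    )


def apply_bias_correction(result: BrainAgeResult, bias: BiasModel) -> BrainAgeResult:
    """Residualize one subject's gap against the fitted age trend."""
    corrected = result.raw_gap - (bias.intercept + bias.alpha * result.chronological_age)
    return replace(result, corrected_gap=float(corrected))


def correct_gaps(gaps: Sequence[float], ages: Sequence[float], bias: BiasModel) -> np.ndarray:
    """Vectorized residualization of many gaps."""
    gaps = np.asarray(gaps, dtype=np.float64)
    ages = np.asarray(ages, dtype=np.float64)
    return gaps - (bias.intercept + bias.alpha * ages)


def control_reference(corrected_control_gaps: Sequence[float]) -> ControlReference:
    """Summarize the control group's corrected gaps (sample SD, n-1)."""
    g = np.asarray(corrected_control_gaps, dtype=np.float64)
    return ControlReference(mean_gap=float(g.mean()), sd_gap=float(g.std(ddof=1)), n=len(g))


def to_zscore(corrected_gaps: Sequence[float], reference: ControlReference) -> np.ndarray:
    """Convert corrected gaps to z-scores against the control reference."""
    g = np.asarray(corrected_gaps, dtype=np.float64)
    return (g - reference.mean_gap) / reference.sd_gap
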