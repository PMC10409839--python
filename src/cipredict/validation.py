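"""Cohort-level model validation and quality-assurance classification.

Mirrors the evaluation a CI centre runs around the prognosis model:

* per-case prediction error at the 6-month endpoint, classified into a
  +/- 10 percentage-point corridor;
* improvement over the preoperative aided score, with statistical
  significance decided by exact binomial critical differences;
* the lower-bound check: WRSmax is a lower estimator of the achievable
  CI score, so a 6-month score significantly *below* WRSmax is a red
  flag;
* "unexpectedly poor" cases — measured score more than 20 points below
  the prediction — and, for those, a rule-based classification of the
  full trajectory (achieved late / delayed increase / flat /
  fluctuating);
* the 3-month QA corridor check performed during basic rehabilitation.

The headline error metric follows the source study's usage: "MAE" is the
MEDIAN absolute error in percentage points, computed overall and
separately for the WRSmax = 0 and WRSmax > 0 subgroups (the model was
developed on patients with residual speech recognition, so the zero
subgroup is expected to validate worse).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression

from . import audiometry
from .audiometry import DEFAULT_ALPHA, DEFAULT_N_ITEMS
from .cohort import FollowUpSeries
from .exceptions import MissingEndpointError, ValidationError
from .model import CoefficientSet, DEFAULT_COEFFICIENTS, PreopProfile, predict_wrs_ci

__all__ = [
    "CaseEvaluation",
    "ValidationSummary",
    "TrajectoryAssessment",
    "TrajectoryThresholds",
    "evaluate_case",
    "summarize_cohort",
    "classify_trajectory",
    "qa_corridor_check",
    "median_absolute_error",
]

#: half-width of the prediction-error corridor, percentage points
CORRIDOR_HALFWIDTH = 10.0

#: shortfall beyond which a case counts as unexpectedly poor, points
POOR_SHORTFALL = 20.0

#: window for matching the 6-month endpoint to an actual visit, months
ENDPOINT_WINDOW = 1.0

CORRIDOR_CATEGORIES = ("within_10", "short_by_more_than_10", "above_by_more_than_10")
TRAJECTORY_PATTERNS = ("achieved_by_12mo", "delayed_increase", "flat", "fluctuating")


@dataclass(frozen=True)
class CaseEvaluation:
    """Six-month evaluation of one case against the prognosis model."""

    patient_id: str
    predicted: float
    measured_6mo: float
    error: float  # measured - predicted, percentage points
    corridor: str
    improvement_vs_ha: float
    significant_improvement: bool
    deterioration: bool
    below_wrsmax_significant: bool
    unexpectedly_poor: bool
    wrs_max: float  # retained for subgroup assignment

    def __post_init__(self) -> None:
        if self.corridor not in CORRIDOR_CATEGORIES:
            raise ValidationError(f"unknown corridor category {self.corridor!r}")


@dataclass(frozen=True)
class TrajectoryThresholds:
    """Tunables of the trajectory rule cascade (all configurable).

    ``achieve_window``: points below prediction still counted as achieved;
    ``slope_min``: late slope (points/month over the last two visits) that
    still suggests delayed achievement; ``fluctuation_sd``: residual SD
    around a monotone fit above which the course counts as fluctuating.
    """

    achieve_window: float = 20.0
    slope_min: float = 2.0
    fluctuation_sd: float = 10.0


@dataclass(frozen=True)
class TrajectoryAssessment:
    patient_id: str
    pattern: str
    slope_late: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.pattern not in TRAJECTORY_PATTERNS:
            raise ValidationError(f"unknown trajectory pattern {self.pattern!r}")


@dataclass(frozen=True)
class ValidationSummary:
    """Cohort-level validation metrics (all errors in percentage points)."""

    n_total: int
    n_wrsmax_zero: int
    n_wrsmax_pos: int
    mae_zero: float | None
    mae_pos: float | None
    mae_all: float
    n_improved_20pp: int
    n_significant_improvement: int
    n_deteriorated: int
    n_below_wrsmax_significant: int
    corridor_counts: dict
    flagged_cases: tuple[str, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flagged_cases"] = list(self.flagged_cases)
        return d


def median_absolute_error(errors: Sequence[float]) -> float:
    """Median of absolute errors, percentage points.

    Deliberately the *median*: the source usage of "MAE" is robust to the
    long error tail of poor performers.
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValidationError("median_absolute_error of an empty set")
    return float(np.median(np.abs(errors)))


def evaluate_case(
    profile: PreopProfile,
    followup: FollowUpSeries,
    coeffs: CoefficientSet = DEFAULT_COEFFICIENTS,
    n_items: int = DEFAULT_N_ITEMS,
    alpha: float = DEFAULT_ALPHA,
    patient_id: str = "",
) -> CaseEvaluation:
    """Evaluate one case at the 6-month endpoint.

    The endpoint is the visit nearest month 6 within +/- 1 month
    (clinical visit jitter); its absence raises MissingEndpointError.
    Comparisons use raw (unrounded) predictions.
    """
    measured = followup.score_at(6.0, window=ENDPOINT_WINDOW)
    if measured is None:
        raise MissingEndpointError(
            f"no follow-up visit within +/-{ENDPOINT_WINDOW} months of month 6 "
            f"for patient {patient_id or '<unnamed>'}"
        )
    predicted = predict_wrs_ci(coeffs, profile).point
    error = measured - predicted
    if error > CORRIDOR_HALFWIDTH:
        corridor = "above_by_more_than_10"
    elif error < -CORRIDOR_HALFWIDTH:
        corridor = "short_by_more_than_10"
    else:
        corridor = "within_10"
    change = audiometry.classify_change(profile.wrs65_ha, measured, n_items, alpha)
    below = audiometry.critical_difference(measured, profile.wrs_max,
                                           n_items, alpha)
    return CaseEvaluation(
        patient_id=patient_id,
        predicted=predicted,
        measured_6mo=measured,
        error=error,
        corridor=corridor,
        improvement_vs_ha=measured - profile.wrs65_ha,
        significant_improvement=(change == "improved"),
        deterioration=(change == "deteriorated"),
        below_wrsmax_significant=bool(below.significant
                                      and measured < profile.wrs_max),
        unexpectedly_poor=bool((predicted - measured) > POOR_SHORTFALL),
        wrs_max=profile.wrs_max,
    )


def summarize_cohort(evaluations: Sequence[CaseEvaluation]) -> ValidationSummary:
    """Aggregate per-case evaluations; invariant under input permutation."""
    if not evaluations:
        raise ValidationError("summarize_cohort requires at least one case")
    zero = [e for e in evaluations if e.wrs_max == 0.0]
    pos = [e for e in evaluations if e.wrs_max > 0.0]
    corridor_counts = {c: 0 for c in CORRIDOR_CATEGORIES}
    for e in evaluations:
        corridor_counts[e.corridor] += 1
    flagged = tuple(sorted(e.patient_id for e in evaluations if e.unexpectedly_poor))
    return ValidationSummary(
        n_total=len(evaluations),
        n_wrsmax_zero=len(zero),
        n_wrsmax_pos=len(pos),
        mae_zero=median_absolute_error([e.error for e in zero]) if zero else None,
        mae_pos=median_absolute_error([e.error for e in pos]) if pos else None,
        mae_all=median_absolute_error([e.error for e in evaluations]),
        n_improved_20pp=sum(e.improvement_vs_ha >= 20.0 for e in evaluations),
        n_significant_improvement=sum(e.significant_improvement for e in evaluations),
        n_deteriorated=sum(e.deterioration for e in evaluations),
        n_below_wrsmax_significant=sum(e.below_wrsmax_significant
                                       for e in evaluations),
        corridor_counts=corridor_counts,
        flagged_cases=flagged,
    )


def classify_trajectory(
    case: CaseEvaluation,
    followup: FollowUpSeries,
    predicted: float | None = None,
    thresholds: TrajectoryThresholds = TrajectoryThresholds(),
) -> TrajectoryAssessment:
    """Classify the follow-up course of an unexpectedly poor case.

    Rule cascade: (1) ``achieved_by_12mo`` if the 12-month score reaches
    the prediction minus the 20-point window; else (2) ``fluctuating``
    if the residual SD around a monotone (isotonic) fit exceeds its
    threshold; else (3) ``delayed_increase`` if the slope over the last
    two visits reaches the slope threshold; else (4) ``flat``.  Only
    cases already flagged unexpectedly poor are assessed, and at least
    three visits including month 12 are required.
    """
    if not case.unexpectedly_poor:
        raise ValidationError(
            "trajectory classification applies only to unexpectedly poor cases")
    if predicted is None:
        predicted = case.predicted
    months = np.asarray(followup.months, dtype=float)
    scores = np.asarray(followup.scores, dtype=float)
    if len(months) < 3:
        raise MissingEndpointError("trajectory classification needs >= 3 visits")
    score_12 = followup.score_at(12.0, window=ENDPOINT_WINDOW)
    if score_12 is None:
        raise MissingEndpointError(
            "trajectory classification needs a visit near month 12")

    fit = isotonic_regression(scores).x
    residual_sd = float(np.std(scores - fit, ddof=0))
    slope_late = float((scores[-1] - scores[-2]) / (months[-1] - months[-2]))

    if score_12 >= predicted - thresholds.achieve_window:
        pattern = "achieved_by_12mo"
    elif residual_sd > thresholds.fluctuation_sd:
        pattern = "fluctuating"
    elif slope_late >= thresholds.slope_min:
        pattern = "delayed_increase"
    else:
        pattern = "flat"
    return TrajectoryAssessment(patient_id=case.patient_id, pattern=pattern,
                                slope_late=slope_late, residual_sd=residual_sd)


def qa_corridor_check(
    profile: PreopProfile,
    measured_3mo: float,
    coeffs: CoefficientSet = DEFAULT_COEFFICIENTS,
    n_items: int = DEFAULT_N_ITEMS,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Early (3-month) quality-assurance check against the expectation corridor.

    The corridor runs from the preoperative WRSmax (a lower estimator of
    the achievable CI score) up to the model prediction.  Returns
    ``below_lower_bound`` when the measured score is significantly below
    WRSmax (critical difference), ``above_prediction`` when it exceeds
    the prediction, ``within_corridor`` otherwise.
    """
    decision = audiometry.critical_difference(measured_3mo, profile.wrs_max,
                                              n_items, alpha)
    if decision.significant and measured_3mo < profile.wrs_max:
        return "below_lower_bound"
    predicted = predict_wrs_ci(coeffs, profile).point
    if measured_3mo > predicted:
        return "above_prediction"
    return "within_corridor"
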