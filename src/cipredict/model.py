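"""Logistic prognosis model for post-implant word recognition.

The model predicts the monosyllabic word recognition score measured in
free field at 65 dB SPL with a cochlear implant six months after
activation, WRS65(CI), from three quantities known before surgery:

* ``wrs_max`` — the maximum word recognition score achievable via
  headphones at any presentation level (%),
* ``age_years`` — age at implantation (years),
* ``wrs65_ha`` — the aided free-field score at 65 dB SPL (%).

The prediction is a logistic function of a linear predictor in raw units:

    WRS65(CI) [%] = 100 / (1 + exp(-(b0 + b1*WRSmax + b2*age + b3*WRS65(HA))))

with the published coefficients b0 = 0.84, b1 = 0.012 /%,
b2 = -0.0094 /year, b3 = 0.0059 /% (standard errors 0.18, 0.0015,
0.0025, 0.0026).  The intercept b0 represents mean word recognition with
CI absent individual corrections; higher age lowers, better preoperative
scores raise, the prediction.  The logistic form keeps every prediction
strictly inside (0, 100).

Besides point prediction this module provides

* a Monte-Carlo uncertainty interval propagating the published
  coefficient standard errors (the source reports no covariance matrix,
  so coefficients are drawn as independent normals — an approximation),
* a maximum-likelihood refit of the same functional form against
  observed scores treated as Binomial(n_items) proportions, used for
  parameter-recovery experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from importlib import resources
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .audiometry import is_attainable
from .exceptions import FitFailureError, ValidationError

__all__ = [
    "CoefficientSet",
    "PreopProfile",
    "PredictionResult",
    "DEFAULT_COEFFICIENTS",
    "default_coefficients",
    "predict_wrs_ci",
    "predict_percent",
    "prediction_interval",
    "refit_coefficients",
]


@dataclass(frozen=True)
class CoefficientSet:
    """The four model coefficients with their standard errors.

    Units: beta0 dimensionless, beta1 per % WRSmax, beta2 per year of
    age, beta3 per % WRS65(HA); each ``se*`` shares its coefficient's
    units and must be non-negative.
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se0: float = 0.0
    se1: float = 0.0
    se2: float = 0.0
    se3: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("se0", "se1", "se2", "se3"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])

    @property
    def ses(self) -> np.ndarray:
        return np.array([self.se0, self.se1, self.se2, self.se3])

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_coefficients() -> CoefficientSet:
    """The published coefficient set, loaded from the packaged config."""
    text = resources.files("cipredict").joinpath(
        "data/default_coefficients.json").read_text(encoding="utf-8")
    return CoefficientSet.from_dict(json.loads(text))


DEFAULT_COEFFICIENTS = default_coefficients()


@dataclass(frozen=True)
class PreopProfile:
    """One patient's preoperative predictors.

    ``fpta_ipsi``/``fpta_contra`` (four-frequency pure-tone averages,
    dB HL) are carried for subgrouping and cohort description; the
    prediction itself uses only the three score/age predictors.  When
    ``n_items`` is given, both scores must be attainable k/n_items
    multiples (the word list's step size).
    """

    wrs_max: float
    wrs65_ha: float
    age_years: float
    fpta_ipsi: float | None = None
    fpta_contra: float | None = None
    n_items: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.wrs_max <= 100.0):
            raise ValidationError(f"wrs_max={self.wrs_max} outside [0, 100] %")
        if not (0.0 <= self.wrs65_ha <= 100.0):
            raise ValidationError(f"wrs65_ha={self.wrs65_ha} outside [0, 100] %")
        if not (self.age_years > 0.0 and math.isfinite(self.age_years)):
            raise ValidationError(f"age_years={self.age_years} must be > 0")
        if self.n_items is not None:
            for name in ("wrs_max", "wrs65_ha"):
                value = getattr(self, name)
                if not is_attainable(value, self.n_items):
                    raise ValidationError(
                        f"{name}={value}% not attainable with a "
                        f"{self.n_items}-item list"
                    )


@dataclass(frozen=True)
class PredictionResult:
    """Point prediction in % with the linear predictor and optional interval."""

    point: float
    linear_predictor: float
    interval_low: float | None = None
    interval_high: float | None = None
    interval_level: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.point < 100.0):
            raise ValidationError("prediction must lie strictly inside (0, 100)")
        if self.interval_low is not None and self.interval_high is not None:
            if not (self.interval_low <= self.point <= self.interval_high):
                raise ValidationError("interval must contain the point prediction")


def predict_percent(coeffs: CoefficientSet, wrs_max, age_years, wrs65_ha):
    """Vectorised model evaluation; returns percent scores in (0, 100)."""
    eta = (coeffs.beta0 + coeffs.beta1 * np.asarray(wrs_max)
           + coeffs.beta2 * np.asarray(age_years)
           + coeffs.beta3 * np.asarray(wrs65_ha))
    return 100.0 / (1.0 + np.exp(-eta))


def predict_wrs_ci(coeffs: CoefficientSet, profile: PreopProfile) -> PredictionResult:
    """Point prediction of WRS65(CI) for a single preoperative profile."""
    eta = (coeffs.beta0 + coeffs.beta1 * profile.wrs_max
           + coeffs.beta2 * profile.age_years + coeffs.beta3 * profile.wrs65_ha)
    point = 100.0 / (1.0 + math.exp(-eta))
    return PredictionResult(point=point, linear_predictor=eta)


def prediction_interval(
    coeffs: CoefficientSet,
    profile: PreopProfile,
    level: float = 0.95,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> PredictionResult:
    """Monte-Carlo uncertainty interval from the coefficient standard errors.

    Coefficients are drawn as independent normals around their point
    values (no covariance is published for the default set), each draw is
    pushed through the logistic model, and the interval is the pair of
    symmetric tail quantiles at the requested level.  With all standard
    errors zero the interval degenerates to the point prediction.
    """
    if not (0.0 < level < 1.0):
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if n_draws < 1000:
        raise ValidationError(f"n_draws must be >= 1000, got {n_draws}")
    base = predict_wrs_ci(coeffs, profile)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=coeffs.betas, scale=coeffs.ses, size=(n_draws, 4))
    x = np.array([1.0, profile.wrs_max, profile.age_years, profile.wrs65_ha])
    eta = draws @ x
    points = 100.0 / (1.0 + np.exp(-eta))
    lo, hi = np.quantile(points, [(1 - level) / 2.0, 1 - (1 - level) / 2.0])
    # finite-sample quantiles can sit a hair off the plug-in point; the
    # reported interval always contains it
    lo = min(float(lo), base.point)
    hi = max(float(hi), base.point)
    return replace(base, interval_low=lo, interval_high=hi, interval_level=level)


# ---------------------------------------------------------------------------
# Maximum-likelihood refit
# ---------------------------------------------------------------------------


def refit_coefficients(
    cohort: Sequence[tuple[PreopProfile, float, int]],
) -> CoefficientSet:
    """Refit the logistic model by maximum likelihood.

    ``cohort`` holds (profile, observed WRS65(CI) in %, n_items) triples.
    Each observed score is treated as a Binomial(n_items) proportion; the
    fit uses the exact raw-unit parameterisation of the prognosis model
    (scores in %, age in years).  Standard errors come from the observed
    information at the optimum.

    Raises FitFailureError on degenerate design (a constant predictor,
    rank deficiency), separation or non-convergence, with diagnostics
    attached.
    """
    if len(cohort) < 4:
        raise FitFailureError(
            "need at least 4 observations to fit 4 coefficients",
            {"n": len(cohort)},
        )
    wrs_max = np.array([p.wrs_max for p, _, _ in cohort], dtype=float)
    age = np.array([p.age_years for p, _, _ in cohort], dtype=float)
    wrs_ha = np.array([p.wrs65_ha for p, _, _ in cohort], dtype=float)
    observed = np.array([obs for _, obs, _ in cohort], dtype=float)
    n_items = np.array([n for _, _, n in cohort], dtype=float)
    if np.any((observed < 0) | (observed > 100)):
        raise ValidationError("observed scores must lie in [0, 100] %")
    if np.any(n_items < 1):
        raise ValidationError("n_items must be >= 1 for every observation")

    X = np.column_stack([np.ones_like(wrs_max), wrs_max, age, wrs_ha])
    names = ("intercept", "wrs_max", "age", "wrs65_ha")
    stds = X[:, 1:].std(axis=0)
    constant = [names[i + 1] for i in range(3) if stds[i] == 0.0]
    if constant:
        raise FitFailureError(
            f"predictor(s) without variation: {', '.join(constant)}",
            {"constant_predictors": constant},
        )
    if np.linalg.matrix_rank(X) < 4:
        raise FitFailureError("rank-deficient design matrix",
                              {"rank": int(np.linalg.matrix_rank(X))})

    glm = sm.GLM(observed / 100.0, X, family=sm.families.Binomial(),
                 var_weights=n_items)
    try:
        res = glm.fit(maxiter=200)
    except PerfectSeparationError as exc:
        raise FitFailureError("perfect separation in refit",
                              {"cause": str(exc)}) from exc
    if not res.converged:
        raise FitFailureError("IRLS did not converge",
                              {"iterations": res.fit_history.get("iteration")})
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))):
        raise FitFailureError(
            "non-finite coefficient or standard error (quasi-separation?)",
            {"params": params.tolist(), "bse": bse.tolist()},
        )
    return CoefficientSet(
        beta0=float(params[0]), beta1=float(params[1]),
        beta2=float(params[2]), beta3=float(params[3]),
        se0=float(bse[0]), se1=float(bse[1]),
        se2=float(bse[2]), se3=float(bse[3]),
        label="refit",
    )
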