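"""Audiometric support computations.

Two independent pieces live here:

* the four-frequency pure-tone average (4FPTA) over 0.5, 1, 2 and 4 kHz,
  with the convention that a threshold beyond the audiometer's output
  limit ("not measurable") is imputed at 130 dB HL before averaging;

* an exact binomial critical-difference engine for monosyllabic word
  recognition scores.  A score obtained with an n-item word list is
  k/n * 100 %, and two scores from the same listener differ significantly
  only if the difference exceeds the measurement noise of two independent
  Binomial(n) experiments.  We model both scores as Binomial(n, p) with a
  common p under the null, estimate p by the pooled maximum-likelihood
  value (k_a + k_b) / (2 n), form the exact distribution of the score
  difference by discrete convolution, and reject when the two-sided tail
  mass at the observed difference is below alpha.  Ties at the rejection
  boundary are treated as non-significant (conservative).  This is an
  exact-binomial implementation of the critical-difference concept used
  in clinical speech audiometry, not a reproduction of any published
  look-up table.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "NOT_MEASURABLE",
    "AudiogramThresholds",
    "CriticalDifferenceDecision",
    "four_freq_pta",
    "critical_difference",
    "classify_change",
    "critical_difference_table",
    "score_to_count",
    "is_attainable",
]

#: Default word-list length (one Freiburg monosyllabic list, 5 % steps).
DEFAULT_N_ITEMS = 20

#: Default two-sided significance level.
DEFAULT_ALPHA = 0.05

#: dB HL value imputed for thresholds beyond the audiometer output limit.
IMPUTED_THRESHOLD_DB = 130.0

#: Measurable threshold range accepted for audiogram entries, dB HL.
THRESHOLD_RANGE_DB = (-10.0, 130.0)


class _NotMeasurable:
    """Singleton marker for a pure-tone threshold beyond audiometer limits."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NM"


NOT_MEASURABLE = _NotMeasurable()


def _check_threshold(value, name: str) -> None:
    if value is NOT_MEASURABLE:
        return
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"audiogram threshold {name} must be a dB HL value or NOT_MEASURABLE, "
            f"got {value!r}"
        ) from None
    lo, hi = THRESHOLD_RANGE_DB
    if not np.isfinite(v) or not (lo <= v <= hi):
        raise ValidationError(
            f"audiogram threshold {name}={value!r} outside measurable range "
            f"[{lo}, {hi}] dB HL"
        )


@dataclass(frozen=True)
class AudiogramThresholds:
    """Air-conduction thresholds at the four octave frequencies, dB HL.

    Each field is either a dB HL value in [-10, 130] or the
    :data:`NOT_MEASURABLE` marker.
    """

    t500: object
    t1000: object
    t2000: object
    t4000: object

    def __post_init__(self) -> None:
        for name in ("t500", "t1000", "t2000", "t4000"):
            _check_threshold(getattr(self, name), name)

    def values_imputed(self) -> tuple[float, float, float, float]:
        """Thresholds with NOT_MEASURABLE replaced by 130 dB HL."""
        out = []
        for name in ("t500", "t1000", "t2000", "t4000"):
            v = getattr(self, name)
            out.append(IMPUTED_THRESHOLD_DB if v is NOT_MEASURABLE else float(v))
        return tuple(out)


def four_freq_pta(audiogram: AudiogramThresholds) -> float:
    """Four-frequency pure-tone average (0.5/1/2/4 kHz), dB HL.

    Arithmetic mean of the four thresholds; a threshold marked
    NOT_MEASURABLE enters as 130 dB HL.
    """
    if not isinstance(audiogram, AudiogramThresholds):
        raise ValidationError("four_freq_pta expects AudiogramThresholds")
    return float(np.mean(audiogram.values_imputed()))


# ---------------------------------------------------------------------------
# Critical differences
# ---------------------------------------------------------------------------


def is_attainable(score_pct: float, n_items: int, tol: float = 1e-6) -> bool:
    """True if ``score_pct`` is a k/n_items multiple of 100 %."""
    if n_items < 1:
        return False
    k = score_pct * n_items / 100.0
    return abs(k - round(k)) <= tol and -tol <= score_pct <= 100.0 + tol


def score_to_count(score_pct: float, n_items: int) -> int:
    """Convert a percent score into the number of correct items.

    Raises ValidationError when the score is not attainable with an
    n_items-word list.
    """
    if n_items < 1:
        raise ValidationError(f"n_items must be >= 1, got {n_items}")
    if not is_attainable(score_pct, n_items):
        raise ValidationError(
            f"score {score_pct}% is not attainable with a {n_items}-item list "
            f"(step size {100.0 / n_items:g}%)"
        )
    return int(round(score_pct * n_items / 100.0))


@dataclass(frozen=True)
class CriticalDifferenceDecision:
    """Outcome of the exact two-sided critical-difference test.

    ``direction`` describes score_b relative to score_a and is ``"none"``
    exactly when the difference is not significant.
    """

    significant: bool
    alpha: float
    n_items_a: int
    n_items_b: int
    direction: str  # "better" | "worse" | "none"
    p_value: float

    def __post_init__(self) -> None:
        if (self.direction == "none") != (not self.significant):
            raise ValidationError("direction must be 'none' iff not significant")


@lru_cache(maxsize=65536)
def _difference_tail_mass(k_a: int, k_b: int, n_items: int) -> float:
    """Exact two-sided tail mass of the score-difference under the pooled null.

    Under H0 both counts are Binomial(n_items, p_pool) with
    p_pool = (k_a + k_b) / (2 n_items).  The pmf of D = K_a - K_b is the
    discrete cross-correlation of the count pmf with itself; the returned
    value is P(|D| >= |k_a - k_b|).
    """
    p_pool = (k_a + k_b) / (2.0 * n_items)
    pmf = stats.binom.pmf(np.arange(n_items + 1), n_items, p_pool)
    # index m of the convolution corresponds to difference d = m - n_items
    diff_pmf = np.convolve(pmf, pmf[::-1])
    d = np.arange(-n_items, n_items + 1)
    d_obs = abs(k_a - k_b)
    return float(diff_pmf[np.abs(d) >= d_obs].sum())


def critical_difference(
    score_a: float,
    score_b: float,
    n_items: int = DEFAULT_N_ITEMS,
    alpha: float = DEFAULT_ALPHA,
) -> CriticalDifferenceDecision:
    """Exact two-sided test of equal recognition probability for two scores.

    Both scores must be attainable with an ``n_items``-word list.  The
    decision is symmetric in (score_a, score_b) up to the reported
    direction.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    k_a = score_to_count(score_a, n_items)
    k_b = score_to_count(score_b, n_items)
    if k_a == k_b:
        return CriticalDifferenceDecision(
            significant=False, alpha=alpha, n_items_a=n_items, n_items_b=n_items,
            direction="none", p_value=1.0,
        )
    p_value = _difference_tail_mass(k_a, k_b, n_items)
    significant = p_value < alpha  # boundary ties conservative
    if not significant:
        direction = "none"
    else:
        direction = "better" if k_b > k_a else "worse"
    return CriticalDifferenceDecision(
        significant=significant, alpha=alpha, n_items_a=n_items,
        n_items_b=n_items, direction=direction, p_value=p_value,
    )


def classify_change(
    preop_score: float,
    postop_score: float,
    n_items: int = DEFAULT_N_ITEMS,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Classify a pre/post score change as improved/unchanged/deteriorated.

    ``improved``/``deteriorated`` require statistical significance under
    :func:`critical_difference`; everything else is ``unchanged``.
    """
    decision = critical_difference(preop_score, postop_score, n_items, alpha)
    if not decision.significant:
        return "unchanged"
    return "improved" if postop_score > preop_score else "deteriorated"


def critical_difference_table(
    n_items: int = DEFAULT_N_ITEMS,
    alpha: float = DEFAULT_ALPHA,
    scores: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Significance look-up table over all attainable score pairs.

    Rows are score_a, columns score_b; cells hold "yes"/"no" for
    significance at the given alpha.
    """
    if scores is None:
        scores = [100.0 * k / n_items for k in range(n_items + 1)]
    scores = list(scores)
    cells = [
        ["yes" if critical_difference(a, b, n_items, alpha).significant else "no"
         for b in scores]
        for a in scores
    ]
    return pd.DataFrame(cells, index=scores, columns=scores)
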