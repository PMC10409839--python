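"""Synthetic patient cohort generator.

No per-patient data accompany the study this package operationalises, so
every downstream stage is exercised on synthetic cohorts that reproduce
the published cohort's demographic and audiometric structure: 124
postlingually deafened adult CI candidates, mean age 65.0 +/- 13.9 years
(range 25-86), mean ipsilateral four-frequency pure-tone average 92 +/-
21 dB HL (range 47-130, unmeasurable thresholds imputed at 130), median
WRSmax 23 % with 39/124 patients at WRSmax = 0, median aided score
WRS65(HA) of 0 % and every WRS65(HA) <= 50 % (the inclusion criterion),
all scores quantised to 5 % steps by the 20-word Freiburg list.

Per-patient pipeline (one shared RNG stream per cohort, seeded from the
config):

1. age ~ truncated normal on the observed range;
2. four pure-tone thresholds around a truncated-normal severity draw;
   thresholds beyond the audiometer limit become NOT_MEASURABLE and the
   4FPTA is computed with the 130 dB HL imputation;
3. WRSmax is exactly zero with probability logistic in the 4FPTA
   (calibrated so ~31 % of the cohort measures zero, rare below
   80 dB HL); otherwise a latent recognition probability decreasing in
   the 4FPTA with listener-level noise on the logit scale;
4. the latent aided probability is an attenuated copy of the WRSmax
   probability (hearing aids transmit only part of the residual
   function); patients whose measured WRS65(HA) exceeds 50 % are
   rejection-resampled (steps 3-5), mirroring cohort selection;
5. measured scores are Binomial(n_items, p)/n_items * 100;
6. the latent CI outcome probability is the prognosis-model prediction
   evaluated at the *measured* preoperative values, as in clinical use;
7. rehabilitation follows a saturating time course
   s(t) = p_ci * (1 - exp(-t / tau)) with a lognormal time constant tau
   (months), sampled binomially at each follow-up visit;
8. a small configurable fraction of patients instead receive an injected
   "flat" trajectory (asymptote far below the prediction) or a
   "fluctuating" one (large zero-mean visit-to-visit perturbations),
   emulating the unexpectedly-poor outcomes the QA workflow must catch.

Calibration constants (parent means of the truncated normals, the two
WRSmax logistic links) were fixed once by a coarse search against the
published cohort summaries and are frozen in the defaults below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .audiometry import (AudiogramThresholds, NOT_MEASURABLE,
                         IMPUTED_THRESHOLD_DB, four_freq_pta)
from .exceptions import GenerationError, ValidationError
from .model import CoefficientSet, DEFAULT_COEFFICIENTS, PreopProfile, predict_percent

__all__ = [
    "GeneratorConfig",
    "SyntheticPatient",
    "FollowUpSeries",
    "default_generator_config",
    "generate_cohort",
    "cohort_to_tables",
]


@dataclass(frozen=True)
class FollowUpSeries:
    """Postoperative WRS65(CI) scores indexed by months since activation."""

    months: tuple[float, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.scores):
            raise ValidationError("months and scores must have equal length")
        m = np.asarray(self.months, dtype=float)
        if len(m) and (np.any(m <= 0) or np.any(np.diff(m) <= 0)):
            raise ValidationError("months must be strictly increasing and > 0")
        s = np.asarray(self.scores, dtype=float)
        if len(s) and (np.any(s < 0) or np.any(s > 100)):
            raise ValidationError("scores must lie in [0, 100] %")

    def score_at(self, month: float, window: float = 0.0) -> float | None:
        """Score at the visit nearest ``month`` within ``+/- window``; None if absent."""
        if not self.months:
            return None
        m = np.asarray(self.months, dtype=float)
        i = int(np.argmin(np.abs(m - month)))
        if abs(m[i] - month) <= window:
            return float(self.scores[i])
        return None


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    profile: PreopProfile
    audiogram: AudiogramThresholds
    latent_p_max: float
    latent_p_ha: float
    latent_p_ci: float
    followup: FollowUpSeries
    injected_pattern: str  # "none" | "flat" | "fluctuating"


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort generator settings; defaults reproduce the published cohort.

    The parent location parameters of the truncated normals differ
    slightly from the target cohort means because truncation to the
    observed range shifts the mean; they were calibrated once so the
    *truncated* means land on 65.0 years and 92 dB HL.
    """

    n_patients: int = 124
    seed: int = 0
    # age at implantation, years
    age_mean: float = 67.45
    age_sd: float = 13.9
    age_range: tuple[float, float] = (25.0, 86.0)
    # ipsilateral hearing-loss severity (latent 4FPTA centre), dB HL
    pta_mean: float = 93.0
    pta_sd: float = 21.0
    pta_range: tuple[float, float] = (47.0, 130.0)
    threshold_offsets: tuple[float, float, float, float] = (-7.5, -2.5, 2.5, 7.5)
    threshold_spread_sd: float = 4.0
    audiometer_max_db: float = 120.0
    # contralateral 4FPTA, dB HL (descriptive passthrough only)
    contra_mean: float = 54.0
    contra_sd: float = 26.0
    contra_range: tuple[float, float] = (3.0, 95.0)
    # P(WRSmax = 0) = logistic(intercept + slope * 4FPTA)
    p_wrsmax_zero_slope: float = 0.08
    p_wrsmax_zero_intercept: float = -8.6
    # latent WRSmax probability, logit scale: intercept + slope * 4FPTA + noise
    wrsmax_logit_intercept: float = 3.8
    wrsmax_logit_slope: float = -0.05
    wrsmax_logit_sd: float = 0.8
    # aided-score link and inclusion criterion
    ha_attenuation: float = 0.15
    max_ha_percent: float = 50.0
    max_resample: int = 1000
    # measurement
    n_items: int = 20
    # rehabilitation trajectory
    trajectory_tau_log_mean: float = 0.0  # median tau = 1 month
    trajectory_tau_log_sd: float = 0.3
    followup_months: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0, 12.0)
    # injected QA patterns
    pattern_rate_flat: float = 0.02
    pattern_rate_fluctuating: float = 0.02
    flat_asymptote_frac: float = 0.3
    fluctuating_level_frac: float = 0.4
    fluctuating_sd: float = 0.15
    # prognosis model used for the latent CI outcome
    coefficients: CoefficientSet = field(default=DEFAULT_COEFFICIENTS)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        if self.n_items < 1:
            raise ValidationError("n_items must be >= 1")
        for name in ("age_range", "pta_range", "contra_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be ordered (lo < hi)")
        if not (0.0 < self.ha_attenuation <= 1.0):
            raise ValidationError("ha_attenuation must be in (0, 1]")
        if self.pattern_rate_flat < 0 or self.pattern_rate_fluctuating < 0 \
                or self.pattern_rate_flat + self.pattern_rate_fluctuating > 1:
            raise ValidationError("pattern rates must be >= 0 and sum to <= 1")
        if any(m <= 0 for m in self.followup_months) or any(
                b <= a for a, b in
                zip(self.followup_months, self.followup_months[1:])):
            raise ValidationError("followup_months must be positive and increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = self.coefficients.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "coefficients" in d and isinstance(d["coefficients"], dict):
            d["coefficients"] = CoefficientSet.from_dict(d["coefficients"])
        for name in ("age_range", "pta_range", "contra_range",
                     "followup_months", "threshold_offsets"):
            if name in d and isinstance(d[name], list):
                d[name] = tuple(d[name])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def default_generator_config() -> GeneratorConfig:
    """The packaged default configuration (identical to ``GeneratorConfig()``)."""
    text = resources.files("cipredict").joinpath(
        "data/default_generator.json").read_text(encoding="utf-8")
    return GeneratorConfig.from_dict(json.loads(text))


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _round_to(x, step):
    return np.round(np.asarray(x) / step) * step


def generate_cohort(config: GeneratorConfig) -> list[SyntheticPatient]:
    """Generate a synthetic cohort; deterministic for a fixed config+seed."""
    cfg = config
    n = cfg.n_patients
    rng = np.random.default_rng(cfg.seed)
    if n == 0:
        return []

    age = np.round(_truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, n), 1)

    # --- audiogram and ipsilateral 4FPTA -----------------------------------
    severity = _truncnorm(rng, cfg.pta_mean, cfg.pta_sd, *cfg.pta_range, n)
    offsets = np.asarray(cfg.threshold_offsets)
    thr = severity[:, None] + offsets[None, :] \
        + rng.normal(0.0, cfg.threshold_spread_sd, size=(n, 4))
    thr = _round_to(thr, 5.0)
    thr = np.maximum(thr, -10.0)
    not_measurable = thr > cfg.audiometer_max_db
    thr_imputed = np.where(not_measurable, IMPUTED_THRESHOLD_DB, thr)
    fpta_ipsi = thr_imputed.mean(axis=1)

    fpta_contra = np.round(
        _truncnorm(rng, cfg.contra_mean, cfg.contra_sd, *cfg.contra_range, n), 1)

    # --- preoperative speech scores with inclusion resampling --------------
    step_pct = 100.0 / cfg.n_items

    def draw_speech(idx):
        m = len(idx)
        p_zero = _sigmoid(cfg.p_wrsmax_zero_intercept
                          + cfg.p_wrsmax_zero_slope * fpta_ipsi[idx])
        zero = rng.uniform(size=m) < p_zero
        logit = (cfg.wrsmax_logit_intercept
                 + cfg.wrsmax_logit_slope * fpta_ipsi[idx]
                 + rng.normal(0.0, cfg.wrsmax_logit_sd, size=m))
        p_max = np.where(zero, 0.0, _sigmoid(logit))
        p_ha = cfg.ha_attenuation * p_max
        k_max = rng.binomial(cfg.n_items, p_max)
        k_ha = rng.binomial(cfg.n_items, p_ha)
        return p_max, p_ha, k_max * step_pct, k_ha * step_pct

    p_max = np.empty(n)
    p_ha = np.empty(n)
    wrs_max = np.empty(n)
    wrs_ha = np.empty(n)
    pending = np.arange(n)
    for attempt in range(cfg.max_resample + 1):
        if pending.size == 0:
            break
        pm, ph, wm, wh = draw_speech(pending)
        p_max[pending], p_ha[pending] = pm, ph
        wrs_max[pending], wrs_ha[pending] = wm, wh
        pending = pending[wh > cfg.max_ha_percent]
    if pending.size:
        raise GenerationError(
            f"inclusion criterion WRS65(HA) <= {cfg.max_ha_percent}% "
            f"unsatisfiable for {pending.size} patients after "
            f"{cfg.max_resample} resampling rounds"
        )

    # --- latent CI outcome and follow-up trajectories ----------------------
    p_ci = np.asarray(
        predict_percent(cfg.coefficients, wrs_max, age, wrs_ha)) / 100.0
    tau = rng.lognormal(cfg.trajectory_tau_log_mean,
                        cfg.trajectory_tau_log_sd, size=n)
    u = rng.uniform(size=n)
    pattern = np.where(
        u < cfg.pattern_rate_flat, "flat",
        np.where(u < cfg.pattern_rate_flat + cfg.pattern_rate_fluctuating,
                 "fluctuating", "none"))

    months = np.asarray(cfg.followup_months, dtype=float)
    rise = 1.0 - np.exp(-months[None, :] / tau[:, None])
    asym = p_ci.copy()
    asym[pattern == "flat"] *= cfg.flat_asymptote_frac
    asym[pattern == "fluctuating"] *= cfg.fluctuating_level_frac
    s = asym[:, None] * rise
    fluct = pattern == "fluctuating"
    if fluct.any():
        s[fluct] += rng.normal(0.0, cfg.fluctuating_sd,
                               size=(int(fluct.sum()), len(months)))
    s = np.clip(s, 0.0, 1.0)
    visit_scores = rng.binomial(cfg.n_items, s) * step_pct

    # --- assemble ----------------------------------------------------------
    width = max(4, len(str(n)))
    patients = []
    for i in range(n):
        vals = [NOT_MEASURABLE if not_measurable[i, j] else float(thr[i, j])
                for j in range(4)]
        audiogram = AudiogramThresholds(*vals)
        profile = PreopProfile(
            wrs_max=float(wrs_max[i]), wrs65_ha=float(wrs_ha[i]),
            age_years=float(age[i]), fpta_ipsi=four_freq_pta(audiogram),
            fpta_contra=float(fpta_contra[i]), n_items=cfg.n_items,
        )
        followup = FollowUpSeries(months=tuple(months),
                                  scores=tuple(float(v) for v in visit_scores[i]))
        patients.append(SyntheticPatient(
            patient_id=f"P{i + 1:0{width}d}", profile=profile,
            audiogram=audiogram, latent_p_max=float(p_max[i]),
            latent_p_ha=float(p_ha[i]), latent_p_ci=float(p_ci[i]),
            followup=followup, injected_pattern=str(pattern[i]),
        ))
    return patients


def cohort_to_tables(cohort: Sequence[SyntheticPatient]):
    """Emit the preoperative and follow-up CSV tables (pandas DataFrames).

    Schemas match the file readers: one preop row per patient, one
    follow-up row per (patient, month); the round trip through the
    readers is lossless.
    """
    from . import io as _io  # local import: io depends on this module's types

    if not cohort:
        raise ValidationError("cohort_to_tables requires a non-empty cohort")
    preop_rows = []
    fu_rows = []
    for pt in cohort:
        thr = {}
        for col, val in zip(_io.THRESHOLD_COLUMNS,
                            (pt.audiogram.t500, pt.audiogram.t1000,
                             pt.audiogram.t2000, pt.audiogram.t4000)):
            thr[col] = _io.NM_MARKER if val is NOT_MEASURABLE else int(val)
        preop_rows.append({
            "patient_id": pt.patient_id,
            "age_years": pt.profile.age_years,
            **thr,
            "fpta_contra": pt.profile.fpta_contra,
            "wrs_max_pct": pt.profile.wrs_max,
            "wrs65_ha_pct": pt.profile.wrs65_ha,
            "n_items": pt.profile.n_items,
        })
        for month, score in zip(pt.followup.months, pt.followup.scores):
            fu_rows.append({"patient_id": pt.patient_id, "month": month,
                            "wrs65_ci_pct": score})
    preop = pd.DataFrame(preop_rows, columns=_io.PREOP_COLUMNS)
    followup = pd.DataFrame(fu_rows, columns=_io.FOLLOWUP_COLUMNS)
    return preop, followup
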