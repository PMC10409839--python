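"""CSV schemas and readers/writers for patient tables.

Two tidy tables carry a cohort:

* the preoperative table, one row per patient, with the four ipsilateral
  pure-tone thresholds ("NM" marks a threshold beyond audiometer
  limits), the optional contralateral 4FPTA, both preoperative speech
  scores in percent, and the word-list length the scores were measured
  with;
* the long-format follow-up table, one row per (patient, month) with the
  postoperative WRS65(CI) in percent.

Scores are stored in percent throughout; the ipsilateral 4FPTA is never
stored but recomputed from the thresholds (with the 130 dB HL
imputation) on read.  Row-level problems are collected with their row
numbers and raised together, so a malformed file reports every offending
row at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .audiometry import (AudiogramThresholds, NOT_MEASURABLE, THRESHOLD_RANGE_DB,
                         four_freq_pta, is_attainable)
from .cohort import FollowUpSeries
from .exceptions import ValidationError
from .model import PreopProfile

__all__ = [
    "PreopRecord",
    "THRESHOLD_COLUMNS",
    "PREOP_COLUMNS",
    "FOLLOWUP_COLUMNS",
    "NM_MARKER",
    "read_preop_table",
    "read_followup_table",
    "write_tables",
]

NM_MARKER = "NM"
THRESHOLD_COLUMNS = ("t500_ipsi", "t1000_ipsi", "t2000_ipsi", "t4000_ipsi")
PREOP_COLUMNS = ("patient_id", "age_years", *THRESHOLD_COLUMNS, "fpta_contra",
                 "wrs_max_pct", "wrs65_ha_pct", "n_items")
FOLLOWUP_COLUMNS = ("patient_id", "month", "wrs65_ci_pct")


@dataclass(frozen=True)
class PreopRecord:
    """A validated preoperative row: the profile plus its audiogram."""

    profile: PreopProfile
    audiogram: AudiogramThresholds | None


class TableValidationError(ValidationError):
    """One or more rows failed validation; carries (row, message) pairs."""

    def __init__(self, path, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {m}" for r, m in problems[:20])
        more = "" if len(problems) <= 20 else f" (+{len(problems) - 20} more)"
        super().__init__(f"{path}: {len(problems)} invalid row(s): {lines}{more}")


def _parse_threshold(raw: str, name: str):
    raw = raw.strip()
    if raw.upper() == NM_MARKER:
        return NOT_MEASURABLE
    try:
        v = float(raw)
    except ValueError:
        raise ValidationError(
            f"{name}={raw!r} is neither a dB HL value nor {NM_MARKER!r}") from None
    lo, hi = THRESHOLD_RANGE_DB
    if not (lo <= v <= hi):
        raise ValidationError(f"{name}={v} outside [{lo}, {hi}] dB HL")
    return v


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_preop_table(path) -> dict[str, PreopRecord]:
    """Read and validate the preoperative table.

    Returns an insertion-ordered mapping patient_id -> PreopRecord.  A
    missing column raises immediately; row-level problems (duplicate
    ids, unattainable scores, malformed numbers) are collected and
    raised together as TableValidationError.
    """
    df = _read_csv(path, PREOP_COLUMNS)
    records: dict[str, PreopRecord] = {}
    problems: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # 1-based, plus header line
        try:
            pid = row["patient_id"].strip()
            if not pid:
                raise ValidationError("empty patient_id")
            if pid in records:
                raise ValidationError(f"duplicate patient_id {pid!r}")
            thresholds = [_parse_threshold(row[c], c) for c in THRESHOLD_COLUMNS]
            audiogram = AudiogramThresholds(*thresholds)
            contra_raw = row["fpta_contra"].strip()
            fpta_contra = float(contra_raw) if contra_raw else None
            n_items = int(row["n_items"])
            wrs_max = float(row["wrs_max_pct"])
            wrs_ha = float(row["wrs65_ha_pct"])
            for name, value in (("wrs_max_pct", wrs_max), ("wrs65_ha_pct", wrs_ha)):
                if not is_attainable(value, n_items):
                    raise ValidationError(
                        f"{name}={value} is not a multiple of the "
                        f"{100.0 / n_items:g}% step of a {n_items}-item list")
            profile = PreopProfile(
                wrs_max=wrs_max, wrs65_ha=wrs_ha,
                age_years=float(row["age_years"]),
                fpta_ipsi=four_freq_pta(audiogram),
                fpta_contra=fpta_contra, n_items=n_items,
            )
            records[pid] = PreopRecord(profile=profile, audiogram=audiogram)
        except (ValidationError, ValueError) as exc:
            problems.append((rowno, str(exc)))
    if problems:
        raise TableValidationError(path, problems)
    return records


def read_followup_table(path, preop_ids) -> tuple[dict[str, FollowUpSeries], list[str]]:
    """Read the long-format follow-up table.

    Returns (series by patient_id, orphan ids).  Series are sorted by
    month regardless of file order; an orphan id (present here, absent
    from the preoperative table) is reported, not fatal; a duplicate
    (patient_id, month) pair is an error.
    """
    preop_ids = set(preop_ids)
    df = _read_csv(path, FOLLOWUP_COLUMNS)
    rows: dict[str, list[tuple[float, float]]] = {}
    problems: list[tuple[int, str]] = []
    seen: set[tuple[str, float]] = set()
    for idx, row in df.iterrows():
        rowno = idx + 2
        try:
            pid = row["patient_id"].strip()
            month = float(row["month"])
            score = float(row["wrs65_ci_pct"])
            if month <= 0 or not math.isfinite(month):
                raise ValidationError(f"month={month} must be > 0")
            if not (0.0 <= score <= 100.0):
                raise ValidationError(f"wrs65_ci_pct={score} outside [0, 100]")
            if (pid, month) in seen:
                raise ValidationError(f"duplicate visit ({pid!r}, month {month:g})")
            seen.add((pid, month))
            rows.setdefault(pid, []).append((month, score))
        except (ValidationError, ValueError) as exc:
            problems.append((rowno, str(exc)))
    if problems:
        raise TableValidationError(path, problems)
    series = {}
    for pid, visits in rows.items():
        visits.sort()
        series[pid] = FollowUpSeries(months=tuple(m for m, _ in visits),
                                     scores=tuple(s for _, s in visits))
    orphans = sorted(pid for pid in series if pid not in preop_ids)
    return series, orphans


def write_tables(preop: pd.DataFrame, followup: pd.DataFrame,
                 preop_path, followup_path) -> None:
    """Write the two cohort tables as UTF-8 CSV (deterministic byte output)."""
    preop.to_csv(preop_path, index=False, encoding="utf-8")
    followup.to_csv(followup_path, index=False, encoding="utf-8")
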