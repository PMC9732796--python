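"""Feasibility-cohort statistics: SINBAD scoring, baseline summaries,
ulcer-free time.

The package ships the 15-patient feasibility cohort table as a CSV fixture
(:func:`load_reference_cohort`), with one row per patient: demographics,
SINBAD score of the last healed ulcer, study-visit counts and the reason
for study incompletion.  Summaries follow the reporting conventions of the
source table: arithmetic mean and sample (n-1) standard deviation, counts
as k/n proportions.

SINBAD is a six-component binary ulcer severity score (Site, Ischemia,
Neuropathy, Bacterial infection, Area, Depth; total 0-6).  A DFU is
classified severe when the total is >= 3.

Time from healing to reulceration is summarised by the Kaplan-Meier
restricted mean (restricted to the largest observed time) with a
nonparametric bootstrap percentile confidence interval, because recurrence
times are administratively censored at 52 weeks of follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from .errors import DomainError, ValidationError

__all__ = [
    "SinbadComponents",
    "COHORT_COLUMNS",
    "sinbad_total",
    "classify_severity",
    "summarize_numeric",
    "NumericSummary",
    "count_by",
    "ulcer_free_time_summary",
    "UlcerFreeTime",
    "load_cohort",
    "load_reference_cohort",
    "cohort_summary",
]


@dataclass(frozen=True)
class SinbadComponents:
    """The six binary SINBAD components (1 = adverse feature present)."""

    site: int = 0
    ischemia: int = 0
    neuropathy: int = 0
    bacterial_infection: int = 0
    area: int = 0
    depth: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1):
                raise ValidationError(
                    f"SINBAD component {f.name!r} must be 0 or 1, got {v!r}"
                )


def sinbad_total(c: SinbadComponents) -> int:
    """Total SINBAD score: the sum of the six binary components (0-6)."""
    return sum(getattr(c, f.name) for f in fields(c))


def classify_severity(score: int) -> str:
    """Classify a SINBAD total: ``"severe"`` iff score >= 3."""
    if score not in range(0, 7):
        raise DomainError(f"SINBAD score must be an integer in 0..6, got {score!r}")
    return "severe" if score >= 3 else "non-severe"


@dataclass(frozen=True)
class NumericSummary:
    mean: float
    sd: float | None
    n: int
    n_missing: int = 0


def summarize_numeric(values: Sequence[float]) -> NumericSummary:
    """Arithmetic mean and sample (n-1) standard deviation.

    Missing values (NaN/None) are excluded and counted.  With a single
    observation the SD is undefined (None); an empty input is an error.
    Rounding is left to the presentation layer.
    """
    arr = pd.to_numeric(pd.Series(list(values)), errors="coerce").to_numpy(float)
    missing = int(np.isnan(arr).sum())
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        raise DomainError("cannot summarise an empty list")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n >= 2 else None
    return NumericSummary(mean=mean, sd=sd, n=n, n_missing=missing)


def count_by(
    records: pd.DataFrame,
    predicate: Callable[[pd.Series], bool] | tuple[str, object],
) -> tuple[int, float]:
    """Count records matching a predicate; returns ``(count, count/n)``.

    ``predicate`` is either a callable over a record row or a
    ``(field, value)`` pair; an unknown field name is an error.
    """
    if isinstance(predicate, tuple):
        field_name, value = predicate
        if field_name not in records.columns:
            raise ValidationError(
                f"unknown field {field_name!r}; columns: {list(records.columns)}"
            )
        mask = records[field_name] == value
    else:
        mask = records.apply(predicate, axis=1)
    k = int(mask.sum())
    return k, k / len(records)


@dataclass(frozen=True)
class UlcerFreeTime:
    """Restricted-mean time to reulceration with bootstrap percentile CI."""

    mean_days: float
    ci_low: float | None
    ci_high: float | None
    restriction_days: float
    n: int
    n_events: int


def ulcer_free_time_summary(
    times: Sequence[float],
    event_flags: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> UlcerFreeTime:
    """Kaplan-Meier restricted mean ulcer-free time (days) with 95% CI.

    The mean of the Kaplan-Meier curve restricted to the largest observed
    time handles administrative censoring at the end of follow-up; the CI
    is a nonparametric bootstrap percentile interval over ``n_boot``
    patient resamples (deterministic given ``seed``); ``n_boot=0`` skips
    the CI.  The point estimate does not depend on the seed.  If no event is observed the KM curve
    never drops and the restricted mean equals the restriction time; a
    warning is issued and the CI is suppressed.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValidationError("times and event_flags must be equal-length 1-D")
    if np.any(t <= 0):
        raise DomainError("times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValidationError("event flags must be 0 (censored) or 1 (event)")
    t_max = float(t.max())

    def rmst(tt, ee) -> float:
        km = KaplanMeierFitter().fit(tt, ee)
        return float(restricted_mean_survival_time(km, t=t_max))

    mean = rmst(t, e)
    if e.sum() == 0:
        warnings.warn(
            "all observations censored: restricted mean equals the "
            "restriction time; CI suppressed"
        )
        return UlcerFreeTime(mean, None, None, t_max, t.size, 0)
    if n_boot <= 0:
        return UlcerFreeTime(mean, None, None, t_max, t.size, int(e.sum()))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, t.size, size=(n_boot, t.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = rmst(t[idx[b]], e[idx[b]])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return UlcerFreeTime(mean, float(lo), float(hi), t_max, t.size, int(e.sum()))


# ---------------------------------------------------------------------------
# Cohort table I/O and the printed-summary table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "study_id",
    "gender",
    "age",
    "ethnicity",
    "bmi",
    "employment",
    "smoking",
    "diabetes_type",
    "year_diagnosis",
    "monofilament_loss",
    "sinbad_score",
    "dfu_study_visits",
    "reason_incomplete",
    "gp_visits",
    "outpatient_visits",
    "hospital_bed_days",
]

_SMOKING = {"Current", "Previous", "Never"}
_MONOFILAMENT = {"None", "Right", "Left", "Both"}
_REASONS = {"Reulceration", "Lost to FU", "Withdrew", ""}


def load_cohort(path) -> pd.DataFrame:
    """Read and validate a per-patient cohort CSV.

    The file must carry exactly the feasibility-table column schema
    (:data:`COHORT_COLUMNS`).  An empty ``reason_incomplete`` means the
    patient completed the study.
    """
    df = pd.read_csv(
        path,
        dtype={"study_id": str},
        keep_default_na=False,
        na_values=[],
    )
    if list(df.columns) != COHORT_COLUMNS:
        raise ValidationError(
            f"cohort columns must be exactly {COHORT_COLUMNS}, got "
            f"{list(df.columns)}"
        )
    for col in ("age", "bmi"):
        df[col] = pd.to_numeric(df[col])
        if (df[col] <= 0).any():
            raise ValidationError(f"{col} must be positive")
    for col in (
        "diabetes_type",
        "year_diagnosis",
        "sinbad_score",
        "dfu_study_visits",
        "gp_visits",
        "outpatient_visits",
        "hospital_bed_days",
    ):
        df[col] = pd.to_numeric(df[col], downcast=None).astype(int)
    if not df["gender"].isin({"M", "F"}).all():
        raise ValidationError("gender must be M or F")
    if not df["smoking"].isin(_SMOKING).all():
        raise ValidationError(f"smoking must be one of {sorted(_SMOKING)}")
    if not df["diabetes_type"].isin({1, 2}).all():
        raise ValidationError("diabetes_type must be 1 or 2")
    if not df["monofilament_loss"].isin(_MONOFILAMENT).all():
        raise ValidationError(
            f"monofilament_loss must be one of {sorted(_MONOFILAMENT)}"
        )
    if not df["sinbad_score"].between(0, 6).all():
        raise ValidationError("sinbad_score must lie in 0..6")
    if not df["reason_incomplete"].isin(_REASONS).all():
        raise ValidationError(
            f"reason_incomplete must be one of {sorted(_REASONS)} (empty = completed)"
        )
    counts = df[["gp_visits", "outpatient_visits", "hospital_bed_days"]]
    if (counts < 0).any().any():
        raise ValidationError("visit/bed-day counts must be non-negative")
    return df


def load_reference_cohort() -> pd.DataFrame:
    """The packaged 15-patient feasibility cohort table."""
    ref = resources.files("dfu_heor.data").joinpath("table5_cohort.csv")
    with resources.as_file(ref) as p:
        return load_cohort(p)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Baseline summary in the reporting layout of the feasibility study.

    Continuous variables as mean (sample SD); categoricals as count and
    proportion of n.  ``severe_last_dfu`` applies the SINBAD >= 3 rule to
    each patient's last healed ulcer.
    """
    n = len(cohort)
    rows = []

    def num(label, col):
        s = summarize_numeric(cohort[col])
        rows.append({"metric": label, "value": s.mean, "sd": s.sd, "n": s.n})

    def cat(label, predicate):
        k, p = count_by(cohort, predicate)
        rows.append({"metric": label, "value": k, "sd": None, "n": n,
                     "proportion": p})

    num("mean_age_years", "age")
    num("mean_bmi", "bmi")
    num("mean_sinbad_score", "sinbad_score")
    cat("female", ("gender", "F"))
    cat("t1dm", ("diabetes_type", 1))
    cat("t2dm", ("diabetes_type", 2))
    cat("smoking_current", ("smoking", "Current"))
    cat("smoking_previous", ("smoking", "Previous"))
    cat("severe_last_dfu", lambda r: classify_severity(r["sinbad_score"]) == "severe")
    cat("completed_study", ("reason_incomplete", ""))
    cat("reulcerated", ("reason_incomplete", "Reulceration"))
    cat("lost_to_followup", ("reason_incomplete", "Lost to FU"))
    cat("withdrew", ("reason_incomplete", "Withdrew"))
    return pd.DataFrame(rows)
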