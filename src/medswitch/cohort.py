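"""ASD cohort identification from medical claims and enrollment data.

A member enters the cohort when all of the following hold:

* **case rule** — at least two claims on *different* service dates carrying an
  ASD diagnostic code (ICD-9 299.x family / ICD-10 F84.x family);
* **enrollment rule** — at least 12 months (365 days) of continuous coverage,
  after merging administratively adjacent spans, overlapping the study window;
* **age rule** — aged 2 to 26 years at the first qualifying ASD claim.

Codes are matched exactly after normalization (dots stripped, upper-cased):
``F84`` matches only the parent code, not ``F84.0``; the default code set
enumerates parent and child codes separately.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .synthetic_data import AGE_BANDS, ICD9_ASD_CODES, ICD10_ASD_CODES

logger = logging.getLogger(__name__)

DEFAULT_STUDY_WINDOW = (dt.date(2012, 1, 1), dt.date(2021, 12, 31))


def normalize_code(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class IcdCodeSet:
    """Normalized ICD-9/ICD-10 code sets used for case finding."""

    icd9: frozenset[str]
    icd10: frozenset[str]

    @classmethod
    def default(cls) -> "IcdCodeSet":
        return cls(
            icd9=frozenset(normalize_code(c) for c in ICD9_ASD_CODES),
            icd10=frozenset(normalize_code(c) for c in ICD10_ASD_CODES),
        )

    @classmethod
    def from_codes(cls, icd9: Iterable[str], icd10: Iterable[str]) -> "IcdCodeSet":
        return cls(
            icd9=frozenset(normalize_code(c) for c in icd9),
            icd10=frozenset(normalize_code(c) for c in icd10),
        )

    def matches(self, code: str, icd_version: int) -> bool:
        norm = normalize_code(code)
        if icd_version == 9:
            return norm in self.icd9
        if icd_version == 10:
            return norm in self.icd10
        return False


def identify_asd_cases(
    medical_claims: pd.DataFrame,
    code_set: Optional[IcdCodeSet] = None,
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW,
) -> pd.DataFrame:
    """Apply the two-claims-on-distinct-dates case rule.

    Parameters
    ----------
    medical_claims
        Columns ``member_id, service_date, icd_version, code`` (one code per
        row; claims with several codes are several rows).
    code_set
        Defaults to the packaged ASD code lists.
    study_window
        Only claims dated inside the window qualify.

    Returns
    -------
    DataFrame with one row per case: ``member_id, first_asd_date,
    n_asd_claim_dates``.  ``first_asd_date`` is the earliest qualifying claim
    date.  Rows with unparseable dates are skipped and counted in a warning.
    """
    if medical_claims.empty:
        return pd.DataFrame(columns=["member_id", "first_asd_date", "n_asd_claim_dates"])
    if code_set is None:
        code_set = IcdCodeSet.default()
    df = medical_claims.copy()
    dates = pd.to_datetime(df["service_date"], errors="coerce")
    n_bad = int(dates.isna().sum())
    if n_bad:
        logger.warning("identify_asd_cases: skipped %d rows with unparseable dates", n_bad)
    df["service_date"] = dates
    df = df[dates.notna()]

    norm = df["code"].astype(str).str.replace(".", "", regex=False).str.strip().str.upper()
    version = pd.to_numeric(df["icd_version"], errors="coerce")
    hit = (version.eq(9) & norm.isin(code_set.icd9)) | (
        version.eq(10) & norm.isin(code_set.icd10)
    )
    lo, hi = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    hit &= df["service_date"].between(lo, hi)
    q = df[hit]
    if q.empty:
        return pd.DataFrame(columns=["member_id", "first_asd_date", "n_asd_claim_dates"])
    grp = q.groupby("member_id")["service_date"]
    out = grp.agg(first_asd_date="min", n_asd_claim_dates="nunique").reset_index()
    out = out[out["n_asd_claim_dates"] >= 2].reset_index(drop=True)
    return out.sort_values("member_id", ignore_index=True)


def _merged_spans(spans: pd.DataFrame) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Merge enrollment spans separated by at most one day."""
    rows = spans.sort_values("start_date")
    merged: list[list[pd.Timestamp]] = []
    for _, r in rows.iterrows():
        s, e = r["start_date"], r["end_date"]
        if pd.isna(s) or pd.isna(e) or e < s:
            raise ValueError("enrollment span with end before start")
        if merged and (s - merged[-1][1]).days <= 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def check_continuous_enrollment(
    enrollment: pd.DataFrame,
    member_id: str,
    min_days: int = 365,
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW,
) -> bool:
    """True iff a merged span overlapping the window covers >= ``min_days``.

    Span length counts both endpoints (a span from Jan 1 to Dec 31 of a
    365-day year has length 365).  A member without spans is simply not
    continuously enrolled.
    """
    spans = enrollment[enrollment["member_id"] == member_id]
    if spans.empty:
        return False
    lo, hi = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    for s, e in _merged_spans(spans):
        if e >= lo and s <= hi and (e - s).days + 1 >= min_days:
            return True
    return False


def continuous_enrollment_flags(
    enrollment: pd.DataFrame,
    min_days: int = 365,
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW,
) -> pd.Series:
    """Vectorized continuous-enrollment flag for every member in the table."""
    df = enrollment.copy()
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    if (df["end_date"] < df["start_date"]).any():
        raise ValueError("enrollment span with end before start")
    df = df.sort_values(["member_id", "start_date"])
    prev_end = df.groupby("member_id")["end_date"].shift()
    new_span = prev_end.isna() | ((df["start_date"] - prev_end).dt.days > 1)
    df["span_id"] = new_span.cumsum()
    merged = df.groupby(["member_id", "span_id"]).agg(
        start_date=("start_date", "min"), end_date=("end_date", "max")
    ).reset_index()
    lo, hi = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    ok = (
        (merged["end_date"] >= lo)
        & (merged["start_date"] <= hi)
        & ((merged["end_date"] - merged["start_date"]).dt.days + 1 >= min_days)
    )
    return ok.groupby(merged["member_id"]).any()


def age_band(age: int) -> Optional[str]:
    for lo, hi, label in AGE_BANDS:
        if lo <= age <= hi:
            return label
    return None


def build_cohort(
    medical_claims: pd.DataFrame,
    enrollment: pd.DataFrame,
    demographics: pd.DataFrame,
    code_set: Optional[IcdCodeSet] = None,
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW,
    age_range: tuple[int, int] = (2, 26),
    min_enroll_days: int = 365,
) -> pd.DataFrame:
    """Intersect the case, enrollment, and age rules.

    Returns one row per cohort member: ``member_id, first_asd_date,
    age_at_first_dx, age_band, sex``.  Ages are computed from birth year at
    the first qualifying ASD claim date.  Cases without a demographics row
    are excluded with a logged count.
    """
    cases = identify_asd_cases(medical_claims, code_set, study_window)
    if cases.empty:
        return pd.DataFrame(
            columns=["member_id", "first_asd_date", "age_at_first_dx", "age_band", "sex"]
        )
    enroll_ok = continuous_enrollment_flags(enrollment, min_enroll_days, study_window)
    cases = cases[cases["member_id"].map(enroll_ok).fillna(False).astype(bool)]

    merged = cases.merge(demographics, on="member_id", how="left")
    missing = merged["birth_year"].isna() | merged["sex"].isna()
    if missing.any():
        logger.warning("build_cohort: %d cases lack demographics; excluded", int(missing.sum()))
        merged = merged[~missing]
    merged["age_at_first_dx"] = (
        merged["first_asd_date"].dt.year - merged["birth_year"].astype(int)
    )
    lo_a, hi_a = age_range
    merged = merged[merged["age_at_first_dx"].between(lo_a, hi_a)]
    merged["age_band"] = merged["age_at_first_dx"].map(age_band)
    out = merged[["member_id", "first_asd_date", "age_at_first_dx", "age_band", "sex"]]
    return out.sort_values("member_id", ignore_index=True)
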