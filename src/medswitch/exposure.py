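"""Drug-class mapping, dispensing episodes, and new-user classification.

Episodes follow the standard persistence convention for pharmacy claims: a
fill extends the open episode when the gap between the end of the previous
fill's supply and the next fill date is under ``gap_days`` (default 30).  The
unadjusted fill-date-to-fill-date convention is available via
``supply_adjusted=False``.

New-user status is tracked at two levels: *new overall* (no recorded use of
the agent at any earlier date, back to the start of available data) and *new
for the year* (no use in the immediately preceding calendar year, i.e.
re-initiation counts).  For SSRIs the washout is evaluated per agent.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .synthetic_data import SGA_AGENTS, SSRI_AGENTS

logger = logging.getLogger(__name__)


def _normalize_name(name: str) -> str:
    return " ".join(str(name).split()).strip().lower()


@dataclass(frozen=True)
class DrugClassMap:
    """Mapping from normalized generic drug name to study class.

    SGA membership is fixed to risperidone and aripiprazole; SSRI membership
    defaults to the six study agents.  Any name not in the map classifies as
    OTHER (with a logged warning), so the OTHER list only needs to cover
    agents that should be recognized silently.
    """

    mapping: dict[str, str]

    @classmethod
    def default(cls, other_agents: tuple[str, ...] = ()) -> "DrugClassMap":
        from .synthetic_data import OTHER_AGENTS

        m = {a: "SGA" for a in SGA_AGENTS}
        m.update({a: "SSRI" for a in SSRI_AGENTS})
        m.update({_normalize_name(a): "OTHER" for a in OTHER_AGENTS})
        m.update({_normalize_name(a): "OTHER" for a in other_agents})
        return cls(mapping=m)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DrugClassMap":
        df = pd.read_csv(path)
        m = {_normalize_name(r["drug_name"]): str(r["class"]).strip().upper()
             for _, r in df.iterrows()}
        bad = {v for v in m.values() if v not in {"SGA", "SSRI", "OTHER"}}
        if bad:
            raise ValueError(f"unknown drug classes in map: {sorted(bad)}")
        return cls(mapping=m)

    def classify(self, name: str) -> str:
        if not str(name).strip():
            raise ValueError("empty drug name")
        norm = _normalize_name(name)
        cls_name = self.mapping.get(norm)
        if cls_name is None:
            logger.warning("unknown drug name %r mapped to OTHER", name)
            return "OTHER"
        return cls_name


def classify_drug(name: str, drug_map: Optional[DrugClassMap] = None) -> str:
    """Class of a single generic drug name (case/whitespace-insensitive)."""
    return (drug_map or DrugClassMap.default()).classify(name)


def classify_claims(
    pharmacy_claims: pd.DataFrame, drug_map: Optional[DrugClassMap] = None
) -> pd.DataFrame:
    """Return the claims with a ``drug_class`` column appended."""
    drug_map = drug_map or DrugClassMap.default()
    df = pharmacy_claims.copy()
    norm = df["drug_name"].astype(str).str.strip().str.lower()
    mapped = norm.map(drug_map.mapping)
    unknown = sorted(norm[mapped.isna()].unique())
    if unknown:
        logger.warning("unknown drug names mapped to OTHER: %s", unknown)
    df["drug_class"] = mapped.fillna("OTHER")
    return df


def build_episodes(
    pharmacy_claims: pd.DataFrame,
    gap_days: int = 30,
    supply_adjusted: bool = True,
) -> pd.DataFrame:
    """Chain fills into dispensing episodes per member and drug.

    A fill joins the open episode iff its gap to the previous fill is under
    ``gap_days``; the gap is ``fill_date - (previous fill_date + previous
    days_supply)`` when ``supply_adjusted`` (default), else the raw
    fill-date difference.  An episode ends at its last fill date plus that
    fill's days supply, so a single-fill episode lasts ``days_supply`` days.

    Returns ``member_id, drug_name, start_date, end_date, n_fills,
    duration_days``; fills with negative days supply are rejected and logged.
    """
    cols = ["member_id", "drug_name", "start_date", "end_date", "n_fills", "duration_days"]
    if pharmacy_claims.empty:
        return pd.DataFrame(columns=cols)
    df = pharmacy_claims.copy()
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    df["days_supply"] = pd.to_numeric(df["days_supply"])
    bad = df["days_supply"] < 0
    if bad.any():
        logger.warning("build_episodes: rejected %d fills with negative days supply",
                       int(bad.sum()))
        df = df[~bad]
    if df.empty:
        return pd.DataFrame(columns=cols)

    df = df.sort_values(["member_id", "drug_name", "fill_date"], kind="mergesort")
    grp = df.groupby(["member_id", "drug_name"], sort=False)
    prev_fill = grp["fill_date"].shift()
    prev_supply = grp["days_supply"].shift()
    if supply_adjusted:
        prev_end = prev_fill + pd.to_timedelta(prev_supply, unit="D")
    else:
        prev_end = prev_fill
    gap = (df["fill_date"] - prev_end).dt.days
    new_episode = prev_fill.isna() | (gap >= gap_days)
    df["episode_id"] = new_episode.cumsum()

    df["supply_end"] = df["fill_date"] + pd.to_timedelta(df["days_supply"], unit="D")
    ep = df.groupby(["member_id", "drug_name", "episode_id"], sort=False).agg(
        start_date=("fill_date", "min"),
        end_date=("supply_end", "last"),
        n_fills=("fill_date", "size"),
    ).reset_index().drop(columns="episode_id")
    ep["duration_days"] = (ep["end_date"] - ep["start_date"]).dt.days
    return ep.sort_values(["member_id", "drug_name", "start_date"], ignore_index=True)


def identify_new_users(
    pharmacy_claims: pd.DataFrame,
    drug_map: Optional[DrugClassMap] = None,
    lookback_start: Optional[dt.date] = None,
    study_window: tuple[dt.date, dt.date] = (dt.date(2012, 1, 1), dt.date(2021, 12, 31)),
    unit: str = "drug",
) -> pd.DataFrame:
    """Flag new users per member, agent (or class), and calendar year.

    For each year in the study window in which the member filled the unit:

    * ``is_new_overall`` — the year of the member's first-ever fill of the
      unit, provided that first fill falls inside the study window (a clean
      lookback);
    * ``is_new_for_year`` — no fill of the unit in the preceding calendar
      year (initiation or re-initiation).

    ``unit`` is ``"drug"`` (per-agent washout, the default; this is the
    washout the class analyses inherit through the initiating agent) or
    ``"class"`` (washout against any agent of the class).
    """
    out_cols = ["member_id", "drug_name", "drug_class", "year",
                "is_new_overall", "is_new_for_year"]
    if pharmacy_claims.empty:
        return pd.DataFrame(columns=out_cols)
    df = classify_claims(pharmacy_claims, drug_map)
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    if lookback_start is not None:
        earliest = df["fill_date"].min().date()
        if earliest > lookback_start:
            logger.warning(
                "identify_new_users: data begin %s, after lookback start %s; "
                "overall flags computed on available data", earliest, lookback_start,
            )
        df = df[df["fill_date"] >= pd.Timestamp(lookback_start)]
    df["year"] = df["fill_date"].dt.year

    if unit == "drug":
        key = df["drug_name"].astype(str).str.strip().str.lower()
    elif unit == "class":
        key = df["drug_class"]
    else:
        raise ValueError("unit must be 'drug' or 'class'")
    df = df.assign(key=key)

    yrs = df.groupby(["member_id", "key"])["year"].agg(["min"]).rename(columns={"min": "first_ever"})
    per_year = df.drop_duplicates(["member_id", "key", "year"])[
        ["member_id", "key", "year", "drug_class"]
    ].merge(yrs, on=["member_id", "key"])
    prev = per_year[["member_id", "key", "year"]].assign(year=lambda d: d["year"] + 1,
                                                         had_prev=True)
    per_year = per_year.merge(prev, on=["member_id", "key", "year"], how="left")
    per_year["had_prev"] = per_year["had_prev"].notna()

    y0, y1 = study_window[0].year, study_window[1].year
    per_year = per_year[per_year["year"].between(y0, y1)]
    per_year["is_new_overall"] = (per_year["year"] == per_year["first_ever"]) & (
        per_year["first_ever"] >= y0
    )
    per_year["is_new_for_year"] = ~per_year["had_prev"]
    per_year["drug_name"] = per_year["key"] if unit == "drug" else pd.NA
    if unit == "class":
        per_year["drug_class"] = per_year["key"]
    return per_year[out_cols].sort_values(
        ["member_id", "drug_name" if unit == "drug" else "drug_class", "year"],
        ignore_index=True,
    )


def summarize_episode_durations(episodes: pd.DataFrame) -> tuple[float, float]:
    """Arithmetic mean and sample SD (ddof=1) of episode durations in days.

    A single episode has SD 0.0 by convention; an empty input is an error.
    """
    if episodes.empty:
        raise ValueError("cannot summarize an empty set of episodes")
    d = episodes["duration_days"].astype(float)
    mean = float(d.mean())
    sd = 0.0 if len(d) < 2 else float(d.std(ddof=1))
    return mean, sd
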