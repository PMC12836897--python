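"""Exposure-group summary tables and the end-to-end pipeline driver.

The summary mirrors the structure of a demographics-by-exposure-group table
for a treated ASD cohort: members are partitioned into ``only_SGA``,
``only_SSRI`` and ``both`` (their union is ``all``), then counted by sex, age
band at first diagnosis, and calendar year, with episode-duration mean (SD)
per group.

Percentage conventions (chosen to reproduce the published worked example):
round-half-even, with demographic rows (sex, age band) at 1 decimal and
group shares / calendar-year rows at 2 decimals.  Demographic denominators
are the group size; calendar-year denominators are that year's treated
total.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional, Union

import pandas as pd

from . import cohort as cohort_mod
from . import exposure as exposure_mod
from . import switching as switching_mod
from .synthetic_data import ClaimsBundle, SimulationConfig, generate_claims

logger = logging.getLogger(__name__)

GROUPS = ("all", "only_SGA", "only_SSRI", "both")


def pct(numerator: float, denominator: float, precision: int = 2) -> float:
    """Percentage with round-half-even at ``precision`` decimals."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-precision)
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_EVEN)
    )


def exposure_groups(
    annual_exposures: pd.DataFrame,
    both_requires_same_year: bool = False,
) -> pd.DataFrame:
    """Assign each SGA/SSRI-treated member to an exposure group.

    ``both`` defaults to person-level dual use (the member received both
    classes at any time), which keeps ``only_SGA + only_SSRI + both = all``.
    With ``both_requires_same_year`` the ``both`` label demands a calendar
    year containing both classes; members whose SGA and SSRI use never share
    a year are then labelled ``both_discordant_years``.
    """
    df = annual_exposures.copy()
    df["has_sga"] = df["classes"].map(lambda c: "SGA" in c)
    df["has_ssri"] = df["classes"].map(lambda c: "SSRI" in c)
    df = df[df["has_sga"] | df["has_ssri"]]
    g = df.groupby("member_id").agg(
        ever_sga=("has_sga", "any"), ever_ssri=("has_ssri", "any")
    )
    g["same_year"] = (df["has_sga"] & df["has_ssri"]).groupby(df["member_id"]).any()

    def label(r):
        if r["ever_sga"] and r["ever_ssri"]:
            if r["same_year"] or not both_requires_same_year:
                return "both"
            return "both_discordant_years"
        return "only_SGA" if r["ever_sga"] else "only_SSRI"

    out = g.apply(label, axis=1).rename("group").reset_index()
    return out.sort_values("member_id", ignore_index=True)


def annual_year_groups(annual_exposures: pd.DataFrame) -> pd.DataFrame:
    """Year-level counts: total treated, only-SGA, only-SSRI, both per year."""
    df = annual_exposures.copy()
    df["has_sga"] = df["classes"].map(lambda c: "SGA" in c)
    df["has_ssri"] = df["classes"].map(lambda c: "SSRI" in c)
    df = df[df["has_sga"] | df["has_ssri"]]
    g = df.groupby("period").agg(total=("member_id", "nunique"))
    g["only_SGA"] = (df["has_sga"] & ~df["has_ssri"]).groupby(df["period"]).sum()
    g["only_SSRI"] = (~df["has_sga"] & df["has_ssri"]).groupby(df["period"]).sum()
    g["both"] = (df["has_sga"] & df["has_ssri"]).groupby(df["period"]).sum()
    return g.reset_index().rename(columns={"period": "year"})[
        ["year", "total", "only_SGA", "only_SSRI", "both"]
    ]


def _tidy_rows(section, row, values, counts, denoms, precision):
    out = []
    for grp in values:
        c, d = counts[grp], denoms[grp]
        out.append((section, str(row), grp, int(c), pct(c, d, precision)))
    return out


def summarize(
    groups: pd.DataFrame,
    cohort: pd.DataFrame,
    episodes: pd.DataFrame,
    annual_exposures: pd.DataFrame,
    cohort_n: Optional[int] = None,
    precision: int = 2,
    demo_precision: int = 1,
) -> pd.DataFrame:
    """Tidy summary table: ``section, row, group, count, pct``.

    ``groups`` comes from :func:`exposure_groups`; ``cohort`` supplies sex
    and age band; ``episodes`` must carry a ``drug_class`` column (episodes
    of non-study drugs are ignored).  ``cohort_n`` is the denominator for
    the treated share (defaults to the cohort size).
    """
    demo = cohort.set_index("member_id")
    gmap = groups.set_index("member_id")["group"]
    members = {grp: set(groups.loc[groups["group"] == grp, "member_id"]) for grp in
               sorted(groups["group"].unique())}
    members["all"] = set(groups["member_id"])
    group_names = ["all"] + [g for g in members if g != "all"]
    n = {g: len(members[g]) for g in group_names}
    if cohort_n is None:
        cohort_n = len(cohort)

    rows = []
    for grp in group_names:
        denom = cohort_n if grp == "all" else n["all"]
        rows.append(("overall", "n", grp, n[grp], pct(n[grp], denom, precision)))

    for value in ("female", "male"):
        sex_members = set(demo.index[demo["sex"] == value])
        counts = {g: len(members[g] & sex_members) for g in group_names}
        rows += _tidy_rows("sex", value, group_names, counts, n, demo_precision)

    for _, _, band in cohort_mod.AGE_BANDS:
        band_members = set(demo.index[demo["age_band"] == band])
        counts = {g: len(members[g] & band_members) for g in group_names}
        rows += _tidy_rows("age", band, group_names, counts, n, demo_precision)

    yg = annual_year_groups(annual_exposures[annual_exposures["member_id"].isin(members["all"])])
    for _, r in yg.iterrows():
        total = int(r["total"])
        rows.append(("year", str(r["year"]), "total", total, pct(total, n["all"], precision)))
        for grp in ("only_SGA", "only_SSRI", "both"):
            rows.append(("year", str(r["year"]), grp, int(r[grp]),
                         pct(int(r[grp]), total, precision)))

    if not episodes.empty:
        ep = episodes
        if "drug_class" in ep.columns:
            ep = ep[ep["drug_class"].isin(["SGA", "SSRI"])]
        ep = ep[ep["member_id"].isin(members["all"])]
        ep_group = ep["member_id"].map(gmap)
        for grp in group_names:
            sub = ep if grp == "all" else ep[ep_group == grp]
            if sub.empty:
                logger.warning("summarize: no episodes for group %s", grp)
                continue
            mean, sd = exposure_mod.summarize_episode_durations(sub)
            rows.append(("episode_duration", "mean", grp, len(sub), round(mean, precision)))
            rows.append(("episode_duration", "sd", grp, len(sub), round(sd, precision)))

    return pd.DataFrame(rows, columns=["section", "row", "group", "count", "pct"])


def summarize_from_counts(
    fixture: dict, precision: int = 2, demo_precision: int = 1
) -> pd.DataFrame:
    """Percentage table computed from a count fixture (same tidy layout).

    Runs the same percentage arithmetic as :func:`summarize` on
    pre-aggregated counts, e.g. the packaged published worked example.
    """
    n = {g: fixture[g] for g in GROUPS}
    rows = []
    rows.append(("overall", "n", "all", n["all"], pct(n["all"], fixture["cohort_n"], precision)))
    for grp in GROUPS[1:]:
        rows.append(("overall", "n", grp, n[grp], pct(n[grp], n["all"], precision)))
    for section, sub in (("sex", fixture["sex"]), ("age", fixture["age"])):
        labels = list(next(iter(sub.values())))
        for row in labels:
            counts = {g: sub[g][row] for g in GROUPS}
            rows += _tidy_rows(section, row, GROUPS, counts, n, demo_precision)
    for year, yc in fixture["year"].items():
        rows.append(("year", str(year), "total", yc["total"],
                     pct(yc["total"], n["all"], precision)))
        for grp in ("only_SGA", "only_SSRI", "both"):
            rows.append(("year", str(year), grp, yc[grp], pct(yc[grp], yc["total"], precision)))
    for grp, (mean, sd) in fixture.get("episode_duration", {}).items():
        rows.append(("episode_duration", "mean", grp, n[grp], mean))
        rows.append(("episode_duration", "sd", grp, n[grp], sd))
    return pd.DataFrame(rows, columns=["section", "row", "group", "count", "pct"])


def run_pipeline(
    config: Optional[SimulationConfig] = None,
    bundle: Optional[ClaimsBundle] = None,
    drug_map: Optional[exposure_mod.DrugClassMap] = None,
    monthly_year: int = 2019,
) -> dict:
    """Drive the full analysis on a bundle (simulated under ``config`` if
    not given): cohort, episodes, new users, annual and monthly exposures,
    switch events, rate series, flow matrices, and the summary table.
    """
    if bundle is None:
        if config is None:
            raise ValueError("provide a config or a bundle")
        bundle = generate_claims(config)
    drug_map = drug_map or exposure_mod.DrugClassMap.default()
    if config is not None:
        window = (config.study_start, config.study_end)
        lookback = config.lookback_start
    else:
        window = cohort_mod.DEFAULT_STUDY_WINDOW
        lookback = None

    cohort = cohort_mod.build_cohort(
        bundle.medical, bundle.enrollment, bundle.demographics, study_window=window
    )
    in_cohort = bundle.pharmacy["member_id"].isin(set(cohort["member_id"]))
    rx = bundle.pharmacy[in_cohort].reset_index(drop=True)
    logger.info("pipeline: %d members in cohort, %d fills retained (%d dropped)",
                len(cohort), int(in_cohort.sum()), int((~in_cohort).sum()))

    episodes = exposure_mod.build_episodes(rx)
    if not episodes.empty:
        norm = episodes["drug_name"].astype(str).str.strip().str.lower()
        episodes["drug_class"] = norm.map(drug_map.mapping).fillna("OTHER")
    new_users_drug = exposure_mod.identify_new_users(
        rx, drug_map, lookback_start=lookback, study_window=window, unit="drug"
    )
    new_users_class = exposure_mod.identify_new_users(
        rx, drug_map, lookback_start=lookback, study_window=window, unit="class"
    )

    expo_year = switching_mod.period_exposures(rx, drug_map, "year")
    expo_month = switching_mod.period_exposures(rx, drug_map, "month", year=monthly_year)
    events_year = switching_mod.detect_switches(expo_year, "year")
    events_month = switching_mod.detect_switches(expo_month, "month")

    rates_class = switching_mod.switching_rate_series(
        events_year, new_users_class, unit="class", granularity="year"
    )
    rates_drug = switching_mod.switching_rate_series(
        events_year, new_users_drug, unit="drug", granularity="year"
    )
    rates_sga_agent = switching_mod.switching_rate_series(
        events_year, new_users_drug, unit="sga_agent", granularity="year"
    )
    monthly_starters = switching_mod.period_starters(
        rx, drug_map, unit="class", granularity="month"
    )
    rates_month = switching_mod.switching_rate_series(
        events_month, monthly_starters, unit="class", granularity="month"
    )

    flows_year = switching_mod.flow_matrix(expo_year, "year")
    flows_month = switching_mod.flow_matrix(expo_month, "month")

    groups = exposure_groups(expo_year)
    summary = summarize(groups, cohort, episodes, expo_year) if not groups.empty else (
        pd.DataFrame(columns=["section", "row", "group", "count", "pct"])
    )
    return {
        "bundle": bundle,
        "cohort": cohort,
        "episodes": episodes,
        "new_users_drug": new_users_drug,
        "new_users_class": new_users_class,
        "exposures_year": expo_year,
        "exposures_month": expo_month,
        "switch_events_year": events_year,
        "switch_events_month": events_month,
        "rates_class_year": rates_class,
        "rates_drug_year": rates_drug,
        "rates_sga_agent_year": rates_sga_agent,
        "rates_class_month": rates_month,
        "flows_year": flows_year,
        "flows_month": flows_month,
        "groups": groups,
        "summary": summary,
    }
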