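"""Period exposures, exclusive class-switch detection, rates, flow matrices.

A *switch* is an exclusive change of psychotropic drug class between two
consecutive periods (calendar years, or calendar months): the member must be
on exactly one class in the baseline period and exactly one *different* class
in the subsequent period.  A period containing fills from more than one class
disqualifies the member for every transition touching that period; absence of
fills in the subsequent period is discontinuation, not a switch.

Class presence is fill-date based: a class is present in a period iff at
least one fill of one of its agents is dated inside the period; days-supply
carryover into the next period is deliberately not modelled.

Agent-level switches between the two SGAs (risperidone <-> aripiprazole) are
detected alongside class-level events whenever both periods are exclusive to
a single SGA agent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exposure import DrugClassMap, classify_claims, identify_new_users

logger = logging.getLogger(__name__)

FLOW_STATES = ("SGA", "SSRI", "OTHER", "absent")


def _period_ordinal(period, granularity: str) -> int:
    """Map a period label to an integer such that consecutive periods differ by 1."""
    if granularity == "year":
        return int(period)
    y, m = str(period).split("-")
    return int(y) * 12 + int(m) - 1


def _period_label(ordinal: int, granularity: str):
    if granularity == "year":
        return int(ordinal)
    return f"{ordinal // 12:04d}-{ordinal % 12 + 1:02d}"


def period_exposures(
    pharmacy_claims: pd.DataFrame,
    drug_map: Optional[DrugClassMap] = None,
    granularity: str = "year",
    year: Optional[int] = None,
) -> pd.DataFrame:
    """Class/agent exposure per member and period.

    Returns one row per member x period with ``classes`` (sorted tuple),
    ``agents`` (sorted tuple), ``n_classes``, and ``exclusive_class`` (set
    iff exactly one class is present, else ``None``).  Periods are calendar
    years (int) or months (``"YYYY-MM"``); ``year`` restricts a monthly
    analysis to one calendar year.
    """
    if granularity not in ("year", "month"):
        raise ValueError("granularity must be 'year' or 'month'")
    cols = ["member_id", "period", "classes", "agents", "n_classes", "exclusive_class"]
    if pharmacy_claims.empty:
        return pd.DataFrame(columns=cols)
    df = classify_claims(pharmacy_claims, drug_map)
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    if granularity == "year":
        df["period"] = df["fill_date"].dt.year
    else:
        df["period"] = df["fill_date"].dt.strftime("%Y-%m")
        if year is not None:
            df = df[df["fill_date"].dt.year == year]
    if df.empty:
        return pd.DataFrame(columns=cols)
    df["drug_norm"] = df["drug_name"].astype(str).str.strip().str.lower()
    g = df.groupby(["member_id", "period"])
    out = g.agg(
        classes=("drug_class", lambda s: tuple(sorted(set(s)))),
        agents=("drug_norm", lambda s: tuple(sorted(set(s)))),
    ).reset_index()
    out["n_classes"] = out["classes"].map(len)
    out["exclusive_class"] = out.apply(
        lambda r: r["classes"][0] if r["n_classes"] == 1 else None, axis=1
    )
    return out.sort_values(["member_id", "period"], ignore_index=True)


def detect_switches(exposures: pd.DataFrame, granularity: str = "year") -> pd.DataFrame:
    """Exclusive class changes (and within-SGA agent changes) between
    consecutive periods.

    Returns one row per event: ``member_id, from_period, to_period,
    from_class, to_class, from_agents, to_agents, from_agent, to_agent,
    level`` where ``level`` is ``"class"`` or ``"agent"``.  ``from_agent`` /
    ``to_agent`` are set when the corresponding period is exclusive to a
    single agent.
    """
    cols = ["member_id", "from_period", "to_period", "from_class", "to_class",
            "from_agents", "to_agents", "from_agent", "to_agent", "level"]
    if exposures.empty:
        return pd.DataFrame(columns=cols)
    df = exposures.copy()
    df["_ord"] = df["period"].map(lambda p: _period_ordinal(p, granularity))
    df = df.sort_values(["member_id", "_ord"], kind="mergesort")
    nxt = df.groupby("member_id")[["_ord", "exclusive_class", "agents", "period"]].shift(-1)
    consecutive = nxt["_ord"] == df["_ord"] + 1
    both_excl = df["exclusive_class"].notna() & nxt["exclusive_class"].notna()

    rows = []
    sel = consecutive & both_excl
    for i in np.flatnonzero(sel.to_numpy()):
        r = df.iloc[i]
        to_cls = nxt["exclusive_class"].iloc[i]
        to_agents = nxt["agents"].iloc[i]
        from_cls = r["exclusive_class"]
        from_agent = r["agents"][0] if len(r["agents"]) == 1 else None
        to_agent = to_agents[0] if len(to_agents) == 1 else None
        to_period = _period_label(int(r["_ord"]) + 1, granularity)
        common = (r["member_id"], r["period"], to_period)
        if to_cls != from_cls:
            rows.append(common + (from_cls, to_cls, r["agents"], to_agents,
                                  from_agent, to_agent, "class"))
        elif (
            from_cls == "SGA"
            and from_agent is not None
            and to_agent is not None
            and from_agent != to_agent
        ):
            rows.append(common + ("SGA", "SGA", r["agents"], to_agents,
                                  from_agent, to_agent, "agent"))
    return pd.DataFrame(rows, columns=cols)


def period_starters(
    pharmacy_claims: pd.DataFrame,
    drug_map: Optional[DrugClassMap] = None,
    unit: str = "class",
    granularity: str = "year",
    year: Optional[int] = None,
) -> pd.DataFrame:
    """Members starting a unit per period: fills in the period, none in the
    immediately preceding period.

    At year granularity this is the per-year new-user rule; the monthly
    variant generalizes it to a one-month washout, for the short-horizon
    switching denominators.
    """
    if pharmacy_claims.empty:
        return pd.DataFrame(columns=["member_id", "key", "period"])
    df = classify_claims(pharmacy_claims, drug_map)
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    if unit == "class":
        df["key"] = df["drug_class"]
    elif unit == "drug":
        df["key"] = df["drug_name"].astype(str).str.strip().str.lower()
    else:
        raise ValueError("unit must be 'class' or 'drug'")
    if granularity == "year":
        df["_ord"] = df["fill_date"].dt.year
    else:
        df["_ord"] = df["fill_date"].dt.year * 12 + df["fill_date"].dt.month - 1
    per = df.drop_duplicates(["member_id", "key", "_ord"])[["member_id", "key", "_ord"]]
    prev = per.assign(_ord=per["_ord"] + 1, had_prev=True)
    per = per.merge(prev, on=["member_id", "key", "_ord"], how="left")
    per = per[per["had_prev"].isna()].drop(columns="had_prev")
    per["period"] = per["_ord"].map(lambda o: _period_label(o, granularity))
    if granularity == "month" and year is not None:
        per = per[per["_ord"] // 12 == year]
    return per[["member_id", "key", "period"]].sort_values(
        ["key", "period", "member_id"], ignore_index=True
    )


def switching_rate_series(
    switch_events: pd.DataFrame,
    new_user_records: pd.DataFrame,
    unit: str = "class",
    granularity: str = "year",
    denominator: str = "auto",
) -> pd.DataFrame:
    """Per-period switching rates: switchers out of a unit over starters of it.

    Parameters
    ----------
    switch_events
        Output of :func:`detect_switches`.
    new_user_records
        Either :func:`period_starters` output (``member_id, key, period``) or
        :func:`medswitch.exposure.identify_new_users` output, in which case
        rows with ``is_new_for_year`` provide the starters.
    unit
        ``"class"`` — one series per drug class, numerator the class-level
        switch events out of that class.
        ``"drug"`` — one series per agent, numerator the class-level events
        whose baseline period is exclusive to that agent; with the default
        denominator the agent's *class* starters are the denominator, so the
        per-agent rates of one class sum to the class rate.
        ``"sga_agent"`` — within-SGA agent switches over the from-agent's own
        starters.
    denominator
        ``"auto"`` (per-unit default as above), ``"class"`` or ``"drug"``.

    Returns ``unit, from_period, to_period, n_switched, n_started, rate``;
    transitions with a zero denominator are omitted and logged.
    """
    if unit not in ("class", "drug", "sga_agent"):
        raise ValueError("unit must be 'class', 'drug' or 'sga_agent'")
    if denominator == "auto":
        denominator = {"class": "class", "drug": "class", "sga_agent": "drug"}[unit]

    starters = new_user_records.copy()
    if "is_new_for_year" in starters.columns:
        starters = starters[starters["is_new_for_year"]]
        key_col = "drug_class" if denominator == "class" else "drug_name"
        starters = starters.rename(columns={key_col: "key", "year": "period"})
    starters = starters[["member_id", "key", "period"]]
    # the last observed period opens no transition: starters there have no
    # subsequent period in which a switch could be seen
    if not starters.empty:
        ords = starters["period"].map(lambda p: _period_ordinal(p, granularity))
        starters = starters[ords < ords.max()]
    den = starters.groupby(["key", "period"])["member_id"].nunique()

    if unit == "class":
        ev = switch_events[switch_events["level"] == "class"].copy()
        ev["unit"] = ev["from_class"]
    elif unit == "drug":
        ev = switch_events[
            (switch_events["level"] == "class") & switch_events["from_agent"].notna()
        ].copy()
        ev["unit"] = ev["from_agent"]
    else:
        ev = switch_events[switch_events["level"] == "agent"].copy()
        ev["unit"] = ev["from_agent"]
    num = ev.groupby(["unit", "from_period"])["member_id"].nunique()

    rows = []
    if unit == "class" or denominator == "drug":
        # the denominator key is also the series unit
        for (key, period), n_started in den.sort_index().items():
            to_period = _period_label(_period_ordinal(period, granularity) + 1, granularity)
            rows.append((key, period, to_period,
                         int(num.get((key, period), 0)), int(n_started)))
    else:
        # per-agent numerators over the agent's class denominator
        classify = DrugClassMap.default().classify
        agents = sorted(ev["unit"].unique())
        for (key, period), n_started in den.sort_index().items():
            to_period = _period_label(_period_ordinal(period, granularity) + 1, granularity)
            for agent in agents:
                if classify(agent) != key:
                    continue
                rows.append((agent, period, to_period,
                             int(num.get((agent, period), 0)), int(n_started)))
    out = pd.DataFrame(rows, columns=["unit", "from_period", "to_period",
                                      "n_switched", "n_started"])
    zero = out["n_started"] == 0
    if zero.any():
        logger.warning("switching_rate_series: omitted %d zero-denominator points",
                       int(zero.sum()))
        out = out[~zero]
    out["rate"] = out["n_switched"] / out["n_started"]
    return out.reset_index(drop=True)


@dataclass
class FlowMatrix:
    """Counts of members moving between exclusive class states.

    ``matrices[(p, q)]`` is a 4x4 DataFrame (SGA, SSRI, OTHER, absent ->
    same) over the consecutive period pair ``p -> q``; members with
    non-exclusive exposure in either period of a pair are excluded from that
    pair.  The member universe is every member appearing in the exposure
    table, so the row sums over destinations equal the number of
    exclusive-or-absent members of the source period who are also
    exclusive-or-absent at the destination.
    """

    granularity: str
    periods: list
    matrices: dict[tuple, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (p, q), m in self.matrices.items():
            for src in FLOW_STATES:
                for dst in FLOW_STATES:
                    rows.append((p, q, src, dst, int(m.loc[src, dst])))
        return pd.DataFrame(rows, columns=["from_period", "to_period",
                                           "from_state", "to_state", "count"])

    def to_sankey_json(self) -> str:
        """Node/link structure consumable by standard Sankey renderers."""
        nodes, index = [], {}
        for p in self.periods:
            for s in FLOW_STATES:
                index[(p, s)] = len(nodes)
                nodes.append({"name": f"{p} {s}", "period": str(p), "state": s})
        links = []
        for (p, q), m in self.matrices.items():
            for src in FLOW_STATES:
                for dst in FLOW_STATES:
                    v = int(m.loc[src, dst])
                    if v:
                        links.append({"source": index[(p, src)],
                                      "target": index[(q, dst)], "value": v})
        return json.dumps({"nodes": nodes, "links": links}, indent=1)


def flow_matrix(
    exposures: pd.DataFrame,
    granularity: str = "year",
    periods: Optional[list] = None,
) -> FlowMatrix:
    """Tabulate exclusive-state transitions over consecutive period pairs."""
    if exposures.empty:
        return FlowMatrix(granularity, periods or [])
    if periods is None:
        ords = sorted({_period_ordinal(p, granularity) for p in exposures["period"]})
        ords = list(range(ords[0], ords[-1] + 1))
        periods = [_period_label(o, granularity) for o in ords]
    members = pd.Index(sorted(exposures["member_id"].unique()))
    by_period = {p: g.set_index("member_id") for p, g in exposures.groupby("period")}

    def states(p):
        s = pd.Series("absent", index=members)
        if p in by_period:
            g = by_period[p]
            s[g.index] = g["exclusive_class"].where(g["n_classes"] == 1, other=pd.NA)
        return s

    fm = FlowMatrix(granularity, list(periods))
    for p, q in zip(periods[:-1], periods[1:]):
        sp, sq = states(p), states(q)
        ok = sp.notna() & sq.notna()
        tab = pd.crosstab(sp[ok], sq[ok]).reindex(
            index=FLOW_STATES, columns=FLOW_STATES, fill_value=0
        )
        fm.matrices[(p, q)] = tab.astype(int)
    return fm
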