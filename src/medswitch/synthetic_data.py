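"""Synthetic longitudinal claims generator.

Emulates the structure of a commercial medical/pharmacy claims database for a
paediatric-to-young-adult autism spectrum disorder (ASD) population: multi-year
enrollment spans, ASD diagnosis claims (ICD-9 299.x / ICD-10 F84.x), and
longitudinal pharmacy fills driven by per-class initiation probabilities,
year-to-year persistence, and class-switch hazards.

The generator records full ground truth (eligibility, per-year class exposure,
switch events, new-user flags) so that every downstream stage of the analysis
pipeline can be validated against a known answer.

Dynamics, per member and calendar year
--------------------------------------
* A member with no active treatment initiates at most one agent per year; the
  agent is drawn from a categorical menu built from ``init_prob``.
* At each treatment start (fresh initiation, class switch-in, re-initiation)
  the member's fate for the *next* year is drawn once: with probability
  ``switch_hazard[class]`` the member appears exclusively on a different class
  next year; for SGA starts, with probability ``sga_agent_switch_hazard`` the
  member swaps to the other SGA agent instead.  Otherwise the member persists
  into the next year with probability ``persist_prob`` or discontinues.
* Discontinuers sit out at least one full calendar year before they may
  re-initiate, so an exclusive-class change across consecutive years occurs
  only through the switch hazard.  This makes the class-switch hazard exactly
  identifiable as (switch events) / (new class starters) downstream.
* Optional co-medication (``p_comedication``) adds a short secondary-class
  fill run to *continuation* years only, producing non-exclusive person-years
  that exercise the single-class exclusivity rules without touching the
  switch-rate estimand.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

# Study drug classes and their agents.  SGAs are restricted to the two agents
# FDA-approved for irritability in ASD; SSRIs are the six agents analysed as a
# single class; OTHER pools everything else (alpha-2 agonists, stimulants, ...).
SGA_AGENTS = ("aripiprazole", "risperidone")
SSRI_AGENTS = (
    "fluoxetine",
    "fluvoxamine",
    "sertraline",
    "citalopram",
    "escitalopram",
    "paroxetine",
)
OTHER_AGENTS = ("clonidine", "guanfacine", "methylphenidate", "atomoxetine", "valproate")
CLASSES = ("SGA", "SSRI", "OTHER")

# Diagnostic code lists used for ASD case finding in claims.
ICD9_ASD_CODES = (
    "299.0", "299.00", "299.01", "299.8", "299.80", "299.81",
    "299.9", "299.90", "299.91", "299", "299.1", "299.10", "299.11",
)
ICD10_ASD_CODES = ("F84", "F84.0", "F84.3", "F84.5", "F84.9", "F84.8")

# Innocuous non-ASD codes used as background diagnostic noise.
_NOISE_CODES_ICD10 = ("Z00.129", "J06.9", "R51")
_NOISE_CODES_ICD9 = ("465.9", "780.60")

AGE_BANDS = ((2, 5, "2-5"), (6, 11, "6-11"), (12, 17, "12-17"), (18, 26, "18-26"))


class SimulationConfig(BaseModel):
    """Parameters of the synthetic claims simulation.

    Defaults emulate the study conditions of the analysis the package
    implements: a 2012-2021 study window with pharmacy history back to 2006,
    a cohort that is ~74% male and mostly diagnosed at school age, and annual
    class-switch hazards of ~6% from SGAs and ~3.4% from SSRIs.
    """

    n_members: int = Field(default=1000, gt=0)
    study_start: dt.date = dt.date(2012, 1, 1)
    study_end: dt.date = dt.date(2021, 12, 31)
    lookback_start: dt.date = dt.date(2006, 1, 1)
    #: distribution over the ASD ICD code list; ``None`` means uniform.
    p_asd_codes: Optional[dict[str, float]] = None
    sex_ratio_male: float = Field(default=0.739, ge=0.0, le=1.0)
    #: weights over the age bands 2-5, 6-11, 12-17, 18-26 at first diagnosis.
    age_band_weights: tuple[float, float, float, float] = (0.071, 0.315, 0.377, 0.237)
    #: per-year initiation probabilities; ``SSRI_by_agent`` applies to each of
    #: the six SSRI agents individually, ``OTHER`` to the pooled other class.
    init_prob: dict[str, float] = Field(
        default_factory=lambda: {
            "SGA_ari": 0.020,
            "SGA_ris": 0.020,
            "SSRI_by_agent": 0.012,
            "OTHER": 0.030,
        }
    )
    persist_prob: float = Field(default=0.65, ge=0.0, le=1.0)
    #: per-year probability that a treatment starter appears exclusively on a
    #: different class the following year; a scalar applies to all classes.
    switch_hazard: Union[float, dict[str, float]] = Field(
        default_factory=lambda: {"SGA": 0.0613, "SSRI": 0.0341, "OTHER": 0.05}
    )
    #: probability that an SGA starter swaps to the other SGA agent next year.
    sga_agent_switch_hazard: float = Field(default=0.013, ge=0.0, le=1.0)
    fills_per_year: int = Field(default=10, gt=0)
    days_supply: int = Field(default=30, gt=0)
    #: probability that a fully enrolled member has a one-month coverage hole.
    enroll_gap_prob: float = Field(default=0.10, ge=0.0, le=1.0)
    #: probability a member meets the two-claims-on-distinct-dates case rule.
    p_case: float = Field(default=0.90, ge=0.0, le=1.0)
    #: probability an initiator also has remote pre-study fills of that agent.
    p_prior_use: float = Field(default=0.05, ge=0.0, le=1.0)
    #: fraction of members with only a short (~6 month) enrollment span.
    p_short_enroll: float = Field(default=0.05, ge=0.0, le=1.0)
    #: fraction of members first diagnosed outside the 2-26 age range.
    p_age_out: float = Field(default=0.03, ge=0.0, le=1.0)
    #: probability a continuation person-year carries secondary-class fills.
    p_comedication: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("age_band_weights")
    @classmethod
    def _weights_sum_to_one(cls, v):
        if any(w < 0 for w in v):
            raise ValueError("age_band_weights must be non-negative")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("age_band_weights must sum to 1 within 1e-9")
        return v

    @field_validator("init_prob")
    @classmethod
    def _init_probs_valid(cls, v):
        required = {"SGA_ari", "SGA_ris", "SSRI_by_agent", "OTHER"}
        missing = required - set(v)
        if missing:
            raise ValueError(f"init_prob missing keys: {sorted(missing)}")
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"init_prob[{k!r}] must be in [0, 1]")
        total = v["SGA_ari"] + v["SGA_ris"] + len(SSRI_AGENTS) * v["SSRI_by_agent"] + v["OTHER"]
        if total > 1.0:
            raise ValueError("init_prob total per-year initiation mass exceeds 1")
        return v

    @field_validator("switch_hazard")
    @classmethod
    def _hazard_valid(cls, v):
        if isinstance(v, dict):
            missing = set(CLASSES) - set(v)
            if missing:
                raise ValueError(f"switch_hazard missing classes: {sorted(missing)}")
            vals = v.values()
        else:
            vals = [v]
        for p in vals:
            if not 0.0 <= p <= 1.0:
                raise ValueError("switch_hazard must be in [0, 1]")
        return v

    @field_validator("p_asd_codes")
    @classmethod
    def _codes_valid(cls, v):
        if v is None:
            return v
        known = set(ICD9_ASD_CODES) | set(ICD10_ASD_CODES)
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"p_asd_codes contains unknown codes: {sorted(unknown)}")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("p_asd_codes must be a probability distribution")
        return v

    @model_validator(mode="after")
    def _dates_ordered(self):
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        if not self.lookback_start <= self.study_start:
            raise ValueError("lookback_start must not be after study_start")
        return self

    def class_hazard(self, cls_name: str) -> float:
        if isinstance(self.switch_hazard, dict):
            return self.switch_hazard[cls_name]
        return float(self.switch_hazard)


@dataclass
class ClaimsBundle:
    """The four claims tables plus generation ground truth.

    Tables (all :class:`pandas.DataFrame`):

    * ``demographics`` — member_id, birth_year, sex
    * ``enrollment`` — member_id, start_date, end_date
    * ``medical`` — member_id, service_date, icd_version, code
    * ``pharmacy`` — member_id, fill_date, drug_name, days_supply
    * ``truth_members`` — per-member eligibility ground truth
    * ``truth_exposures`` — per member-year class/agent exposure with
      ``started`` (treatment start this year) and ``will_switch_class``
    * ``truth_switches`` — realized switch events (kind: class | agent)
    * ``truth_new_users`` — per member-agent-year new-user flags
    """

    demographics: pd.DataFrame
    enrollment: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame
    truth_members: pd.DataFrame
    truth_exposures: pd.DataFrame
    truth_switches: pd.DataFrame
    truth_new_users: pd.DataFrame

    _TABLES = (
        "demographics", "enrollment", "medical", "pharmacy",
        "truth_members", "truth_exposures", "truth_switches", "truth_new_users",
    )
    _DATE_COLS = {
        "enrollment": ["start_date", "end_date"],
        "medical": ["service_date"],
        "pharmacy": ["fill_date"],
    }

    def write_csv(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, indir: Union[str, Path]) -> "ClaimsBundle":
        indir = Path(indir)
        tables = {}
        for name in cls._TABLES:
            df = pd.read_csv(indir / f"{name}.csv")
            for col in cls._DATE_COLS.get(name, []):
                df[col] = pd.to_datetime(df[col])
            tables[name] = df
        return cls(**tables)


def _span_days(spans: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Intersect ordinal-day spans with [lo, hi]."""
    out = []
    for a, b in spans:
        a2, b2 = max(a, lo), min(b, hi)
        if a2 <= b2:
            out.append((a2, b2))
    return out


def _sample_days(rng, spans, k, distinct=False, max_tries=200):
    """Sample k ordinal days uniformly from a union of inclusive spans."""
    lens = np.array([b - a + 1 for a, b in spans], dtype=np.int64)
    total = int(lens.sum())
    if total <= 0:
        return []
    if distinct and k > total:
        k = total
    cum = np.cumsum(lens)
    picked: set[int] = set()
    out = []
    tries = 0
    while len(out) < k and tries < max_tries:
        tries += 1
        u = int(rng.integers(0, total))
        i = int(np.searchsorted(cum, u, side="right"))
        day = spans[i][0] + (u - (cum[i - 1] if i else 0))
        if distinct:
            if day in picked:
                continue
            picked.add(day)
        out.append(day)
    return sorted(out) if distinct else out


def _month_span(year: int, month: int) -> tuple[int, int]:
    first = dt.date(year, month, 1).toordinal()
    last = (dt.date(year + (month == 12), month % 12 + 1, 1) - dt.timedelta(days=1)).toordinal()
    return first, last


def generate_claims(config: SimulationConfig) -> ClaimsBundle:
    """Simulate a claims bundle under ``config``.

    Deterministic for a fixed ``config.seed``: a single PCG64 stream seeded
    through ``numpy.random.SeedSequence(seed)`` drives generation member by
    member in member-id order.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    y0, y1 = config.study_start.year, config.study_end.year
    study_lo = config.study_start.toordinal()
    study_hi = config.study_end.toordinal()
    lookback_lo = config.lookback_start.toordinal()

    # initiation menu: (class, agent, probability)
    ip = config.init_prob
    menu: list[tuple[str, str, float]] = [
        ("SGA", "aripiprazole", ip["SGA_ari"]),
        ("SGA", "risperidone", ip["SGA_ris"]),
    ]
    menu += [("SSRI", a, ip["SSRI_by_agent"]) for a in SSRI_AGENTS]
    menu += [("OTHER", a, ip["OTHER"] / len(OTHER_AGENTS)) for a in OTHER_AGENTS]
    menu_probs = np.array([p for _, _, p in menu])
    menu_cum = np.cumsum(menu_probs)
    total_init = float(menu_cum[-1])

    if config.p_asd_codes is None:
        code_list = list(ICD9_ASD_CODES) + list(ICD10_ASD_CODES)
        code_probs = np.full(len(code_list), 1.0 / len(code_list))
    else:
        code_list = list(config.p_asd_codes)
        code_probs = np.array([config.p_asd_codes[c] for c in code_list])

    demo_rows, enroll_rows, med_rows, rx_rows = [], [], [], []
    tm_rows, te_rows, ts_rows, tnu_rows = [], [], [], []

    for idx in range(config.n_members):
        mid = f"M{idx:06d}"

        # ---- enrollment -------------------------------------------------
        short = rng.random() < config.p_short_enroll
        if short:
            start = int(rng.integers(study_lo, study_hi - 179))
            spans = [(start, start + 179)]
        else:
            spans = [(lookback_lo, study_hi)]
            if rng.random() < config.enroll_gap_prob:
                gy = int(rng.integers(y0, y1 + 1))
                gm = int(rng.integers(1, 13))
                mlo, mhi = _month_span(gy, gm)
                spans = _span_days(spans, lookback_lo, mlo - 1) + _span_days(
                    spans, mhi + 1, study_hi
                )
        for a, b in spans:
            enroll_rows.append(
                (mid, dt.date.fromordinal(a).isoformat(), dt.date.fromordinal(b).isoformat())
            )
        study_spans = _span_days(spans, study_lo, study_hi)
        # longest span (as generated the spans are already maximal) >= 365 days?
        enroll_ok = any(b - a + 1 >= 365 for a, b in spans)

        if study_spans:
            first_y = dt.date.fromordinal(study_spans[0][0]).year
            last_y = dt.date.fromordinal(study_spans[-1][1]).year
        else:
            first_y, last_y = y0, y0 - 1
        year_spans = {
            y: _span_days(study_spans, dt.date(y, 1, 1).toordinal(), dt.date(y, 12, 31).toordinal())
            for y in range(first_y, last_y + 1)
        }
        active_years = [y for y in range(first_y, last_y + 1) if year_spans[y]]

        # ---- demographics and medical claims ----------------------------
        sex = "male" if rng.random() < config.sex_ratio_male else "female"
        is_case = rng.random() < config.p_case
        if is_case:
            k = int(rng.integers(2, 5))
            days = _sample_days(rng, study_spans, k, distinct=True)
        else:
            if rng.random() < 0.5:
                days = _sample_days(rng, study_spans, 1, distinct=True)
            else:  # two claims on the same date: fails the case definition
                days = _sample_days(rng, study_spans, 1, distinct=True) * 2
        asd_dates = [dt.date.fromordinal(d) for d in days]
        for d in asd_dates:
            ci = int(rng.choice(len(code_list), p=code_probs))
            code = code_list[ci]
            version = 10 if code.startswith("F") else 9
            med_rows.append((mid, d.isoformat(), version, code))
        # background non-ASD claims
        for d in _sample_days(rng, study_spans, int(rng.integers(0, 3))):
            if rng.random() < 0.7:
                code, version = _NOISE_CODES_ICD10[int(rng.integers(0, 3))], 10
            else:
                code, version = _NOISE_CODES_ICD9[int(rng.integers(0, 2))], 9
            med_rows.append((mid, dt.date.fromordinal(d).isoformat(), version, code))

        age_out = rng.random() < config.p_age_out
        if age_out:
            age = int(rng.integers(27, 41))
        else:
            bi = int(rng.choice(4, p=np.array(config.age_band_weights)))
            lo_a, hi_a, _ = AGE_BANDS[bi]
            age = int(rng.integers(lo_a, hi_a + 1))
        anchor_year = min(asd_dates).year if asd_dates else active_years[0]
        birth_year = anchor_year - age
        demo_rows.append((mid, birth_year, sex))

        effective_case = is_case and len({d for d in asd_dates}) >= 2
        eligible = effective_case and enroll_ok and not age_out and bool(asd_dates)
        first_asd = min(asd_dates).isoformat() if effective_case and asd_dates else ""

        # ---- pharmacy dynamics ------------------------------------------
        state: Optional[tuple[str, str]] = None  # (class, agent) active this year
        pend: Optional[str] = None  # action scheduled for next year
        cooldown = False
        init_year: Optional[int] = None
        fill_years: dict[str, set[int]] = {}
        member_rx: list[tuple[int, str, str]] = []  # (day, agent, class)

        for i, year in enumerate(active_years):
            consecutive = i > 0 and active_years[i - 1] == year - 1
            if not consecutive:
                # a coverage break resets treatment state
                state, pend, cooldown = None, None, False
            started = False
            if state is None:
                if cooldown:
                    cooldown = False
                elif rng.random() < total_init:
                    j = int(np.searchsorted(menu_cum, rng.random() * total_init, side="right"))
                    j = min(j, len(menu) - 1)
                    state = (menu[j][0], menu[j][1])
                    started = True
                    fresh_start = True
            else:
                if pend == "class":
                    from_cls, from_agent = state
                    others = [c for c in CLASSES if c != from_cls]
                    new_cls = others[int(rng.integers(0, 2))]
                    agents = {"SGA": SGA_AGENTS, "SSRI": SSRI_AGENTS, "OTHER": OTHER_AGENTS}[new_cls]
                    new_agent = agents[int(rng.integers(0, len(agents)))]
                    ts_rows.append(
                        (mid, year - 1, year, from_cls, new_cls, from_agent, new_agent, "class")
                    )
                    state = (new_cls, new_agent)
                    started = True
                    fresh_start = True
                elif pend == "agent":
                    from_cls, from_agent = state
                    new_agent = [a for a in SGA_AGENTS if a != from_agent][0]
                    ts_rows.append(
                        (mid, year - 1, year, "SGA", "SGA", from_agent, new_agent, "agent")
                    )
                    state = ("SGA", new_agent)
                    started = True
                    fresh_start = False  # within-class change: class clock keeps running
                else:
                    if rng.random() < config.persist_prob:
                        pass
                    else:
                        state, cooldown = None, True
            if state is None:
                pend = None
                continue

            cls_name, agent = state
            if started:
                if init_year is None:
                    init_year = year
                r = rng.random()
                h_cls = config.class_hazard(cls_name) if fresh_start else 0.0
                h_agent = config.sga_agent_switch_hazard if cls_name == "SGA" else 0.0
                if r < h_cls:
                    pend = "class"
                elif r < h_cls + h_agent:
                    pend = "agent"
                else:
                    pend = None
            else:
                pend = None

            n_fills = 1 + int(rng.poisson(max(config.fills_per_year - 1, 0)))
            for d in _sample_days(rng, year_spans[year], n_fills):
                member_rx.append((d, agent, cls_name))
            fill_years.setdefault(agent, set()).add(year)
            te_rows.append((mid, year, cls_name, agent, started, pend == "class", False))

            # secondary-class fills in continuation years only
            if not started and config.p_comedication > 0 and rng.random() < config.p_comedication:
                others = [c for c in CLASSES if c != cls_name]
                cls2 = others[int(rng.integers(0, 2))]
                agents2 = {"SGA": SGA_AGENTS, "SSRI": SSRI_AGENTS, "OTHER": OTHER_AGENTS}[cls2]
                agent2 = agents2[int(rng.integers(0, len(agents2)))]
                for d in _sample_days(rng, year_spans[year], int(rng.integers(1, 3))):
                    member_rx.append((d, agent2, cls2))
                fill_years.setdefault(agent2, set()).add(year)
                te_rows.append((mid, year, cls2, agent2, False, False, True))

        # ---- remote prior use (lookback fills) ---------------------------
        prior_agent = ""
        if init_year is not None and not short and rng.random() < config.p_prior_use:
            # placed at least one full year before the study window so the
            # per-year re-initiation flag at study entry is unaffected
            prior_hi = dt.date(y0 - 2, 12, 31).toordinal()
            prior_spans = _span_days(spans, lookback_lo, prior_hi)
            if prior_spans:
                first_agent = min(
                    (a for a in fill_years), key=lambda a: (min(fill_years[a]), a)
                )
                for d in _sample_days(rng, prior_spans, int(rng.integers(1, 3))):
                    member_rx.append((d, first_agent, ""))
                    fill_years.setdefault(first_agent, set()).add(dt.date.fromordinal(d).year)
                prior_agent = first_agent

        for d, agent, _cls in sorted(member_rx):
            rx_rows.append((mid, dt.date.fromordinal(d).isoformat(), agent, config.days_supply))

        # ---- ground-truth new-user flags ---------------------------------
        for agent, yrs in sorted(fill_years.items()):
            first_ever = min(yrs)
            for year in sorted(yrs):
                if year < y0:
                    continue
                tnu_rows.append(
                    (
                        mid,
                        agent,
                        year,
                        year == first_ever and first_ever >= y0,
                        (year - 1) not in yrs,
                    )
                )

        tm_rows.append(
            (
                mid, is_case, effective_case, enroll_ok, age, not age_out, eligible,
                first_asd, init_year if init_year is not None else -1, prior_agent,
            )
        )

    demographics = pd.DataFrame(demo_rows, columns=["member_id", "birth_year", "sex"])
    enrollment = pd.DataFrame(enroll_rows, columns=["member_id", "start_date", "end_date"])
    enrollment["start_date"] = pd.to_datetime(enrollment["start_date"])
    enrollment["end_date"] = pd.to_datetime(enrollment["end_date"])
    medical = pd.DataFrame(med_rows, columns=["member_id", "service_date", "icd_version", "code"])
    medical["service_date"] = pd.to_datetime(medical["service_date"])
    pharmacy = pd.DataFrame(rx_rows, columns=["member_id", "fill_date", "drug_name", "days_supply"])
    pharmacy["fill_date"] = pd.to_datetime(pharmacy["fill_date"])
    truth_members = pd.DataFrame(
        tm_rows,
        columns=[
            "member_id", "case_intent", "is_case", "enroll_ok", "age_at_first_dx",
            "age_ok", "eligible", "first_asd_date", "init_year", "prior_use_agent",
        ],
    )
    truth_exposures = pd.DataFrame(
        te_rows,
        columns=["member_id", "year", "drug_class", "drug_name", "started",
                 "will_switch_class", "secondary"],
    )
    truth_switches = pd.DataFrame(
        ts_rows,
        columns=["member_id", "from_period", "to_period", "from_class", "to_class",
                 "from_agent", "to_agent", "kind"],
    )
    truth_new_users = pd.DataFrame(
        tnu_rows, columns=["member_id", "drug_name", "year", "is_new_overall", "is_new_for_year"]
    )
    return ClaimsBundle(
        demographics, enrollment, medical, pharmacy,
        truth_members, truth_exposures, truth_switches, truth_new_users,
    )


def table1_fixture() -> dict:
    """Published worked-example counts for the treated ASD cohort.

    Counts of individuals prescribed SGAs and/or SSRIs in a 2012-2021 US
    commercial-claims ASD cohort of 24,730 individuals, by exposure group,
    sex, age band at first ASD diagnosis, and calendar year.  Used to test
    the summary-table arithmetic on a known answer.
    """
    return {
        "cohort_n": 24730,
        "all": 15976,
        "only_SGA": 2662,
        "only_SSRI": 9387,
        "both": 3927,
        "sex": {
            "all": {"female": 4171, "male": 11805},
            "only_SGA": {"female": 506, "male": 2156},
            "only_SSRI": {"female": 2725, "male": 6662},
            "both": {"female": 940, "male": 2987},
        },
        "age": {
            "all": {"2-5": 1136, "6-11": 5033, "12-17": 6028, "18-26": 3779},
            "only_SGA": {"2-5": 280, "6-11": 908, "12-17": 847, "18-26": 627},
            "only_SSRI": {"2-5": 550, "6-11": 2770, "12-17": 3705, "18-26": 2362},
            "both": {"2-5": 306, "6-11": 1355, "12-17": 1476, "18-26": 790},
        },
        "year": {
            2012: {"total": 1707, "only_SGA": 507, "only_SSRI": 924, "both": 276},
            2013: {"total": 2292, "only_SGA": 610, "only_SSRI": 1313, "both": 369},
            2014: {"total": 2597, "only_SGA": 599, "only_SSRI": 1577, "both": 421},
            2015: {"total": 2971, "only_SGA": 699, "only_SSRI": 1797, "both": 475},
            2016: {"total": 3619, "only_SGA": 795, "only_SSRI": 2313, "both": 511},
            2017: {"total": 4619, "only_SGA": 953, "only_SSRI": 2998, "both": 668},
            2018: {"total": 5943, "only_SGA": 1286, "only_SSRI": 3638, "both": 1019},
            2019: {"total": 7469, "only_SGA": 1541, "only_SSRI": 4678, "both": 1250},
            2020: {"total": 6838, "only_SGA": 1261, "only_SSRI": 4518, "both": 1059},
            2021: {"total": 6970, "only_SGA": 1217, "only_SSRI": 4678, "both": 1075},
        },
        "episode_duration": {
            "all": (230.91, 314.44),
            "only_SGA": (221.86, 301.93),
            "only_SSRI": (226.86, 305.73),
            "both": (237.94, 327.21),
        },
    }
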