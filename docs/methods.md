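# Methods

This note documents the analytic conventions, the synthetic-data model, and
the design decisions behind `medswitch`.

## Cohort definition

A member is an ASD case when at least two medical claims on **different**
service dates carry an ASD diagnostic code inside the study window.  Codes
are matched **exactly** after normalization (dots removed, upper-cased) and
per ICD version: the default set enumerates parent and child codes
separately (ICD-9 299, 299.0, 299.00, 299.01, 299.1, 299.10, 299.11, 299.8,
299.80, 299.81, 299.9, 299.90, 299.91; ICD-10 F84, F84.0, F84.3, F84.5,
F84.8, F84.9), so `F84` does not prefix-match `F84.0`, and an ICD-10 claim
coded `299` does not match the ICD-9 entry.  Exact matching keeps the
behaviour of a code-list override predictable (removing a code can only
shrink the cohort, a property the test suite asserts).

Continuous enrollment merges spans separated by ≤ 1 day (adjacent monthly
segments are administratively continuous) and requires a merged span of at
least 365 days — a fixed, documented constant standing in for "12 months" —
that overlaps the study window.  Any overlap qualifies; the alternative
reading (the full 365 days inside the window) is not implemented because the
source analysis does not specify it.

Age eligibility (2–26 years) is evaluated at the first qualifying ASD claim,
computed from birth year; this is the only diagnosis-related anchor the
summary table reports, and no other anchor is defined.

## Exposure conventions

* **Classes.** SGA = {risperidone, aripiprazole} (fixed); SSRI = the six
  named agents; every other agent pools into OTHER.  Unknown drug names map
  to OTHER with a logged warning rather than failing, because claims
  dictionaries routinely contain agents outside the study set.
* **Episodes.** Per member × drug, fills chain while the gap from the end of
  the previous fill's supply (`fill_date + days_supply`) to the next fill is
  under 30 days.  Supply-adjusted gaps are the standard persistence
  convention; the unadjusted fill-date-to-fill-date variant is available via
  `supply_adjusted=False` since the source rule ("gap of less than 30 days")
  does not say which it used.  An episode ends at its last fill date plus
  that fill's supply, so a single-fill episode lasts `days_supply` days and
  episode duration is always positive.
* **New users.** Washout is evaluated per agent (using the same SSRI again
  spoils the overall washout; a different SSRI does not).  Class-level
  analyses use a pooled variant (`unit="class"`) in which any agent of the
  class counts.  *New overall* additionally requires that the first-ever
  fill falls inside the study window.
* **Period exposure.** A class is present in a year/month iff at least one
  fill is dated inside it.  Days-supply carryover across a period boundary
  is deliberately ignored: the analysis counts prescriptions per period, and
  modelling carryover would change the exclusivity semantics of the switch
  definition.

## Switching

A class switch requires exclusive exposure to one class in period *t* and
exclusive exposure to a different class in period *t + 1* (consecutive at
the chosen granularity).  "No overlapping prescriptions" is operationalized
as *no period containing fills of both classes*; a stricter days-supply
overlap test is out of scope.  Absence in *t + 1* is discontinuation, never
a switch.  Within-SGA agent switches are detected when both periods are
exclusive to a single SGA agent and the agents differ.

The rate series divides, per transition *t → t + 1*, the members switching
out of a unit by the members **newly starting** that unit in *t*.  The last
observed period opens no transition and is excluded from the denominators.
For per-agent series the default denominator is the agent's *class* starter
count, so the per-agent rates of one class sum to the class rate (the
convention that makes agent-level decompositions additive); the agent's own
starter count is available via `denominator="drug"`.  The monthly
denominator generalizes the yearly rule to a one-month washout; an
all-users-in-source-month denominator can be formed from the period
exposures if wanted.  Series are indexed by the FROM unit.

Flow matrices count transitions between the states {SGA, SSRI, OTHER,
absent} over all members appearing in the exposure table; members with more
than one class in a period are excluded from every pair touching that
period, mirroring the mutually-exclusive bars of a treatment-pathway Sankey
diagram.

## Statistics

Both statistics use midranks for ties.  The rank-sum statistic `W` is the
sum of pooled ranks of the first group; the exact two-sided p-value
enumerates all `C(n, n_A)` assignments of the pooled ranks (used whenever
that count is ≤ 200,000, which always covers pooled samples of 16 and the
9-vs-9 series of a ten-year study), doubling the smaller tail and capping at
1.  Larger samples use the tie-corrected normal approximation with
continuity correction.  Spearman's ρ is the Pearson correlation of the time
ranks with the midranked rates; its p-value is a full permutation
enumeration for n ≤ 8 and a seeded Monte-Carlo permutation otherwise.  A
constant rate series has no defined rank correlation and is returned
flagged, not silently zeroed.

## Synthetic-data model

The generator simulates each member's treatment career at **calendar-year
resolution** with a small state machine:

* An untreated member initiates at most one agent per year, drawn from a
  categorical menu built from `init_prob` (per-year probabilities:
  aripiprazole 0.020, risperidone 0.020, each SSRI agent 0.012, OTHER class
  0.030).  These defaults put roughly two-thirds of an eligible cohort on an
  SGA or SSRI at some point over a ten-year window, matching the treated
  share such cohorts report.
* At every treatment start (fresh initiation, class switch-in, or
  re-initiation) the next year's fate is drawn once: switch class with
  probability `switch_hazard[class]` (defaults SGA 0.0613, SSRI 0.0341,
  OTHER 0.05 — the class-level annual switching rates the analysis is
  designed to detect), swap to the other SGA agent with probability
  `sga_agent_switch_hazard` (0.013), otherwise persist into the next year
  with probability `persist_prob` (0.65) or discontinue.
* Discontinuers sit out at least one full year before re-initiating, and
  within-class agent swaps do not restart the class-switch clock.  Both
  rules exist to make the switch hazard *exactly* identifiable as
  (detected switch events) ÷ (new class starters): every class starter
  carries the hazard once, and no exclusive-class change can arise by any
  other route.  The parameter-recovery tests (20 seeds × 5,000 members at
  hazards 0, 0.06, 0.12) rest on this identity.
* Optional co-medication (`p_comedication`, default 0) adds a short
  secondary-class fill run to *continuation* years only, creating the
  non-exclusive person-years that exercise the exclusivity rules without
  touching the rate estimand.  Tests that need polypharmacy enable it
  explicitly.
* Fills are placed uniformly within the year (avoiding enrollment holes),
  `1 + Poisson(fills_per_year − 1)` per active year with a fixed
  `days_supply` of 30 days.  The default of 10 fills per active year models
  near-monthly refills with imperfect adherence.  Uniform placement
  deliberately produces inter-fill gaps on both sides of the 30-day episode
  rule.
* Demographics: male fraction 0.739 and age-band weights
  (0.071, 0.315, 0.377, 0.237) over 2–5 / 6–11 / 12–17 / 18–26 years,
  the composition reported for treated ASD claims cohorts.  Structured
  eligibility violations are injected at documented rates: members failing
  the two-distinct-dates case rule (10%), short (~6-month) enrollment (5%),
  a one-month coverage hole (10%), first diagnosis outside 2–26 (3%), and
  remote pre-study use of the first agent (5%, placed at least one full
  calendar year before the study so the per-year re-initiation flag at study
  entry is unaffected).

A single PCG64 stream seeded through `SeedSequence(seed)` drives generation
member by member, so a fixed seed reproduces a byte-identical bundle.

### What the generator does and does not emulate

It reproduces the *structural* features the pipeline depends on: eligibility
rules with violators, per-agent washout histories, exclusive and
non-exclusive person-years, and class/agent switch dynamics with known
hazards.  It does **not** emulate: within-year class changes (dynamics are
year-resolution, so monthly switching on default synthetic data is
structurally zero — monthly detection is validated on constructed claims
instead); time-varying hazards (trend statistics on synthetic data are
null-calibrated rather than reproducing any published trend); realistic
adherence patterns (uniform fill placement fragments episodes more than real
refill behaviour, so synthetic episode durations average ~110 days rather
than the ~230 days real cohorts show); and correlations between demographics
and treatment.  Passing tests therefore certify the analysis logic, not the
realism of any particular rate printed from synthetic data.

## Summary-table conventions

Exposure groups are person-level: `both` defaults to "received both classes
at any time", which keeps `only_SGA + only_SSRI + both = all` exactly.  The
alternative year-level reading ("both classes in the same calendar year") is
available via `both_requires_same_year=True`; members whose SGA and SSRI use
never share a year are then reported as their own `both_discordant_years`
row, because assigning them to either "only" group would contradict its
definition.  Calendar-year rows always use year-level classification.

Percentages are round-half-even, with demographic rows (sex, age band) at
1 decimal and group shares / calendar-year rows at 2 decimals — the
precision mix that exactly reproduces the packaged worked-example table.
Demographic denominators are the group size; calendar-year denominators are
that year's treated total; the treated share uses the full cohort size.
Episode-duration rows report the arithmetic mean and sample SD (ddof = 1;
a single episode has SD 0 by convention).

## Problem sizes

Default test and reproduction sizes were chosen so the whole suite runs in a
few minutes on one CPU: 400-member bundles for ground-truth equivalence
tests, 5,000 members for distributional checks and parameter recovery
(20 seeds per hazard in the tests, 10 in the reproduction script), 100 seeds
of 30-member bundles for brute-force oracle comparisons, and 500 random fill
sets for the episode-split oracle.

## Known limitations

* Monthly analyses of default synthetic data detect no switches (see above).
* The generator draws each member's initiation independently each year;
  secular trends in prescribing volume are not modelled.
* Drug names are matched as normalized generic strings; NDC codes, brand
  names, dose and formulation are out of scope.
* The exclusivity rule is period-based; two prescriptions whose supplies
  overlap across a period boundary are not treated as concurrent.
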