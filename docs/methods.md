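# Methods

## The sequence model

A utilization sequence is a per-patient directed graph. Nodes are
patient–provider contacts with day-resolution timestamps (ISO-8601 at every
boundary) and a provider at one of six levels (GP, allied health, ambulatory
specialist, hospital outpatient, hospital inpatient, other; each level has a
distinct rank used as the vertical axis in pathway plots). Edges are typed
information flows: `REFERRAL`, `REPORT`, `FOLLOWUP`. A follow-up edge runs
from the contact at which the appointment was made to the realized follow-up
contact, so all three types are uniformly time-forward.

Contacts are totally ordered by `(timestamp, contact_id)`. Same-day contacts
are allowed — routine data routinely contains a GP and a specialist visit on
the same day — and an edge between same-day contacts is legal iff the source
precedes the destination in this total order. Any edge set respecting the
order is acyclic; `build_sequence` still asserts acyclicity independently
(stdlib topological sort) rather than relying on the argument, and
`validate_sequence` re-checks it via networkx. Validation reports violations
(named invariant + offending element) instead of raising, so data-QA
pipelines can collect them.

## Measures

* **Inter-visit intervals**: the n−1 day gaps between consecutive contacts,
  optionally restricted to one provider level; gaps are ≥ 0 and, unfiltered,
  sum to the first-to-last span.
* **Provider involvement**: distinct provider ids and distinct levels.
* **Continuity of information**: |{contacts with in-degree ≥ 1}| / (n − 1).
  In a time-forward DAG "has an edge from a temporally preceding contact" is
  logically equivalent to "has at least one incoming edge", so the in-degree
  scan is exact. The denominator excludes the initial contact (it cannot be
  preceded). A singleton sequence has no meaningful continuity and reports a
  missing value, not 0 or 1. All three edge types count equally; parallel
  edges between a pair count once. Per-type edge counts are reported so
  users can build restricted variants.
* **Threads**: weakly connected components of the graph (direction ignored:
  a referral without a report back still ties two contacts into one strand
  of care). Isolated contacts are singleton threads.
* **Summary window**: half-open `[start, end)`; default is
  `[first contact, last contact + 1 day)`, so `observation_days = span + 1`
  and `contacts_per_year = n * 365 / observation_days`. For cohort-level
  rate comparisons of simulated data the explicit simulation window
  `[day 0, horizon)` is used instead: under the span default a singleton
  sequence annualizes to 365 contacts/year and would dominate cohort means.

`to_traditional_measures` reduces a sequence to per-window visit counts and
binary used-a-level flags — the measures the sequence model generalizes.

## Simulator

The simulator is a per-patient discrete-event process over `[day 0,
horizon)`; its purpose is to emulate routine-data event logs under two
structurally different regimes so that every measure is testable without
access to real claims.

Mechanics (all draws from the patient's own RNG substream):

* **Summoning threads.** Chronic patients hold a GP monitoring thread;
  intervals are normal around the preset mean with sd = 20% of the mean,
  floored at 7 days. The first thread contact is drawn uniform(0, mean) —
  the stationary-renewal start — so the expected contact count over horizon
  H is exactly H/μ, which the rate-recovery test checks (500 patients,
  within 5% of 365/28). Each monitoring contact links to its successor with
  a FOLLOWUP edge with probability `p_gp_followup`. Under the free-access
  preset chronic patients additionally hold
  `n_regular_specialists_chronic = 3` specialist threads (91-day mean,
  complete FOLLOWUP chains — the quarterly summons is explicit).
* **Acute events** arrive Poisson at `lambda_acute_per_year`. Non-chronic
  patients act on an event with probability `p_acute_nonchronic_gp`;
  chronic patients always act, but an event within 7 days before the next
  scheduled monitoring contact is folded into it (the acute reason is
  appended — "collected reasons" — instead of spawning a contact; a folded
  event is fully absorbed, including any specialist need). An event needs
  specialist care with probability `p_acute_specialist_need`; such an event
  goes directly to a specialist with probability `p_direct_specialist`
  (forced 0 under gatekeeping), otherwise it produces a GP contact followed
  by a referred specialist contact 7–28 days later, with a REFERRAL edge
  recorded with probability `p_referral_info`. The non-direct branch refers
  onward in both regimes: in the free-access regime referrals exist but are
  sparsely informative (`p_referral_info = 0.3`), which is exactly the
  structural contrast the presets encode.
* **Reports.** Every specialist contact sends a REPORT edge to the
  patient's next GP contact on a strictly later day with probability
  `p_report_back`; without a realized destination before the horizon the
  report is dropped (debug-logged).
* **Degenerate case.** A patient with no activity receives one index GP
  contact at a uniform random day, so every patient yields a valid
  (possibly singleton) sequence; a never-attending population is outside
  the model.
* **Reproducibility.** Patient *i* uses `numpy.default_rng([seed, i])`:
  independent substreams keyed by a counter, so growing a cohort preserves
  the prefix and identical configs serialize byte-identically.

### Preset parameters

Structural parameters are fixed by the regimes being encoded: gatekeeping
on/off; GP summoning means of 28 d (free-access, "every four weeks") and
32 d (gatekept, "four, five weeks"); 3 regular specialists at 91-day
summoning vs none (GP-retained chronic care); information-flow
probabilities 0.3/0.4 (referral info / report back, free access) vs
0.95/0.95 (gatekept, electronic letters both ways).

The remaining rates are free knobs calibrated once by
`scripts/calibrate.py` (simulated cohorts of 2000/regime, fixed seed)
against two utilization anchors — a free-access : gatekept ratio of mean
annual contacts of at least 3, and a chronic-patient median of at least 25
contacts/year under the free-access preset — and then frozen:

| knob | germany_like | norway_like |
|---|---|---|
| `lambda_acute_per_year` | 8.0 | 2.0 |
| `p_acute_nonchronic_gp` | 0.95 | 0.3 |
| `p_acute_specialist_need` | 0.4 | 0.2 |
| `p_direct_specialist` | 0.7 | 0 (gatekeeping) |
| `p_gp_followup` | 0.8 | 0.9 |

`p_acute_specialist_need` is this package's own addition to the preset
vocabulary: without a probability routing acute events to specialist care,
a gatekept regime could generate no referral chains at all. At the frozen
values the calibration run reports a ratio of 3.31 and a chronic median of
31.0 contacts/year; the directional contrasts (gatekept continuity higher;
free-access provider counts and thread counts higher) follow from the
structure rather than the calibration and are asserted over 2000-patient
cohorts per regime.

### What the simulator does and does not emulate

It emulates the event-log *structure* of routine data: summoning rhythms,
referral chains, missing reports, fragmented threads, heavy chronic
utilization. It does not emulate seasonality, hospitalization episodes,
co-payment effects, provider capacity, geographic variation, or coded
diagnoses (reasons are free-text labels and never interpreted). Passing
tests therefore demonstrate correctness of the measures and the qualitative
regime contrasts, not calibration to any real national claims data.

## Aggregation

Per-stratum (generic attribute keys) descriptives: mean, median, IQR
(q75 − q25), fraction missing, per numeric summary field. Missing values
(e.g. continuity of singletons) are excluded from moments and counted in
the missing fraction; weighted means over strata therefore reconstruct the
pooled mean exactly (medians exempt). `compare_regimes` reports both means,
their difference and the ratio A/B per measure, with the ratio missing when
the denominator mean is 0. Because the event-table schema carries no
covariates, stratification keys travel in an optional patient side-table
(`patient_id` + one column per attribute) written by `careseq simulate
--out-attributes` and attached by `careseq measure --attributes`.

## Numerical and design notes

* Windowing is half-open everywhere; inverted windows are argument errors.
* Intervals are integers (dates); interval draws round to int days.
* Thread output order is deterministic (by earliest contact).
* CSV writers fix column order and row order; missing values serialize as
  empty fields; `\n` line endings — byte-identical output for identical
  cohorts.
* Strict parsing: every malformed row is reported with its CSV line number;
  nothing is silently dropped. The one lenient rule: an *empty* provider
  level maps to OTHER with a logged warning (missing levels are common in
  routine extracts), while an unknown non-empty level is an error.
* Problem sizes in the shipped tests (1500 random graphs for the oracle
  suite, 10^4 simulated patients for structural validity, 2000/regime for
  the regime contrasts, 500 for rate recovery, 1000 for the chronic
  median) keep the full suite around ten seconds on one CPU while holding
  Monte-Carlo error well inside the asserted margins.

## Known limitations

* Continuity credits any backward link equally; no weighting by path length
  or edge type (per-type counts allow users to recompute variants).
* The simulator's acute process is memoryless and regime parameters are
  time-invariant over the horizon.
* Heuristic inference of information edges from claims lacking explicit
  linkage fields is out of scope: the reader expects recorded links.
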