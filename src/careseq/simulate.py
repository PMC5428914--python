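"""Regime-parameterized cohort simulator.

Generates synthetic per-patient utilization sequences under a *regime
preset*: the parameter bundle encoding one health system's structural rules.
Two presets ship with the package, encoding the qualitative contrast between
a gatekept, GP-centred system ("norway_like": obligatory referrals, rich
electronic information flow, chronic care retained by the family physician)
and a free-access system ("germany_like": facultative and sparsely
informative referrals, reports back often missing, chronic care shifted to
several regularly-summoning ambulatory specialists).

The generative process per patient over ``[day 0, horizon)``:

* Chronic patients hold a GP monitoring thread: the family physician summons
  the patient at roughly regular intervals (normal around the preset mean,
  sd = 20% of the mean, floored at 7 days).  The first thread contact falls
  uniformly within one mean interval of day 0 — the stationary-renewal start,
  so the expected thread contact count over a horizon H is exactly H/mu.
  Each monitoring contact makes the next appointment (a FOLLOWUP edge to its
  successor) with probability ``p_gp_followup``.
* Where the preset grants chronic patients regular specialists
  (``n_regular_specialists_chronic`` > 0), each specialist runs its own
  summoning thread at ``specialist_followup_interval_days`` with a complete
  FOLLOWUP chain (the quarterly summons is explicit).
* Acute care-seeking events arrive as a Poisson process at
  ``lambda_acute_per_year``.  Non-chronic patients act on an event with
  probability ``p_acute_nonchronic_gp``; chronic patients always act, but an
  event landing within 7 days of the next scheduled monitoring contact is
  folded into it (the acute reason is appended to that contact — "collected"
  reasons — instead of spawning a new contact).  An event needs specialist
  care with probability ``p_acute_specialist_need``; such an event either
  goes directly to a specialist (probability ``p_direct_specialist``, forced
  0 under gatekeeping) or produces a GP contact followed by a referred
  specialist contact 7-28 days later, with a REFERRAL edge recorded with
  probability ``p_referral_info`` (referral paperwork does not always carry
  usable information).  All other events produce a plain GP contact.
* Every specialist contact sends a report back to the patient's next GP
  contact (a REPORT edge) with probability ``p_report_back``; with no later
  GP contact before the horizon the report has no realized destination and
  is dropped.
* A patient with no activity at all receives one index GP contact at a
  uniform random day, so every patient yields a valid (possibly singleton)
  sequence.

Reproducibility: one root seed; patient *i* draws from an independent
substream seeded ``(root_seed, i)`` via numpy's SeedSequence, so enlarging a
cohort never reshuffles earlier patients.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from .model import (
    Contact,
    EdgeType,
    InfoEdge,
    Provider,
    ProviderLevel,
    UtilizationSequence,
    build_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalSpec",
    "RegimePreset",
    "PatientProfile",
    "CohortConfig",
    "DEFAULT_CHRONIC_FRACTION",
    "germany_like_preset",
    "norway_like_preset",
    "load_preset",
    "simulate_patient",
    "simulate_cohort",
]

#: Shipped default cohort mix: fraction of patients with a chronic condition.
DEFAULT_CHRONIC_FRACTION = 0.3

#: Day 0 of every simulated sequence maps to this calendar date.
EPOCH = datetime.date(2000, 1, 3)

_SPECIALTIES = ("cardiology", "nephrology", "oncology", "orthopedics", "urology")


@dataclass(frozen=True)
class IntervalSpec:
    """Mean and jitter (sd) of a summoning interval, in days."""

    mean: float
    sd: float

    @classmethod
    def around(cls, mean: float) -> "IntervalSpec":
        # Default jitter: 20% of the mean.
        return cls(mean=mean, sd=0.2 * mean)


@dataclass
class RegimePreset:
    """Parameter bundle encoding a health-system regime for simulation.

    Probabilities lie in [0, 1]; intervals and the acute rate are strictly
    positive; ``gatekeeping`` forces ``p_direct_specialist`` to 0 (specialist
    access requires a GP referral).
    """

    name: str
    gatekeeping: bool
    p_direct_specialist: float
    gp_followup_interval_days: IntervalSpec
    p_gp_followup: float
    n_regular_specialists_chronic: int
    specialist_followup_interval_days: IntervalSpec
    p_referral_info: float
    p_report_back: float
    lambda_acute_per_year: float
    p_acute_nonchronic_gp: float
    p_acute_specialist_need: float

    def validate(self) -> None:
        probs = {
            "p_direct_specialist": self.p_direct_specialist,
            "p_gp_followup": self.p_gp_followup,
            "p_referral_info": self.p_referral_info,
            "p_report_back": self.p_report_back,
            "p_acute_nonchronic_gp": self.p_acute_nonchronic_gp,
            "p_acute_specialist_need": self.p_acute_specialist_need,
        }
        for key, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{key}={p} outside [0, 1]")
        for key, spec in (
            ("gp_followup_interval_days", self.gp_followup_interval_days),
            ("specialist_followup_interval_days", self.specialist_followup_interval_days),
        ):
            if spec.mean <= 0 or spec.sd <= 0:
                raise ValueError(f"{key} mean and sd must be > 0, got {spec}")
        if self.lambda_acute_per_year <= 0:
            raise ValueError(
                f"lambda_acute_per_year={self.lambda_acute_per_year} must be > 0"
            )
        if self.n_regular_specialists_chronic < 0:
            raise ValueError("n_regular_specialists_chronic must be >= 0")
        if self.gatekeeping and self.p_direct_specialist != 0.0:
            raise ValueError(
                "gatekeeping forces p_direct_specialist == 0, got "
                f"{self.p_direct_specialist}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RegimePreset":
        data = dict(data)
        for key in ("gp_followup_interval_days", "specialist_followup_interval_days"):
            value = data[key]
            if isinstance(value, dict):
                data[key] = IntervalSpec(**value)
            elif isinstance(value, (int, float)):
                data[key] = IntervalSpec.around(float(value))
        preset = cls(**data)
        preset.validate()
        return preset


@dataclass
class PatientProfile:
    patient_id: str
    chronic: bool
    covariates: dict = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Configuration of one simulated cohort."""

    n_patients: int
    regime: RegimePreset
    chronic_fraction: float = DEFAULT_CHRONIC_FRACTION
    horizon_days: int = 365
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if not 0.0 <= self.chronic_fraction <= 1.0:
            raise ValueError("chronic_fraction must lie in [0, 1]")
        self.regime.validate()


def germany_like_preset() -> RegimePreset:
    """Free-access regime: no gatekeeping, specialist-shifted chronic care.

    Monthly GP summoning for chronic patients, three regular specialists each
    summoning quarterly, facultative and sparsely informative referrals, and
    reports back that often go missing.  Rates not fixed by the regime's
    structural rules (the acute care-seeking rate and routing probabilities)
    are calibration outputs frozen by ``scripts/calibrate.py``.
    """
    return RegimePreset(
        name="germany_like",
        gatekeeping=False,
        p_direct_specialist=0.7,
        gp_followup_interval_days=IntervalSpec.around(28.0),
        p_gp_followup=0.8,
        n_regular_specialists_chronic=3,
        specialist_followup_interval_days=IntervalSpec.around(91.0),
        p_referral_info=0.3,
        p_report_back=0.4,
        lambda_acute_per_year=8.0,
        p_acute_nonchronic_gp=0.95,
        p_acute_specialist_need=0.4,
    )


def norway_like_preset() -> RegimePreset:
    """Gatekept regime: obligatory referrals, GP-retained chronic care.

    Four-to-five-week GP summoning, no regular ambulatory specialists
    (specialist involvement only via referral to hospital outpatient
    clinics), and near-complete electronic information flow in both
    directions.  Calibration-frozen rates as for the germany-like preset.
    """
    return RegimePreset(
        name="norway_like",
        gatekeeping=True,
        p_direct_specialist=0.0,
        gp_followup_interval_days=IntervalSpec.around(32.0),
        p_gp_followup=0.9,
        n_regular_specialists_chronic=0,
        specialist_followup_interval_days=IntervalSpec.around(91.0),
        p_referral_info=0.95,
        p_report_back=0.95,
        lambda_acute_per_year=2.0,
        p_acute_nonchronic_gp=0.3,
        p_acute_specialist_need=0.2,
    )


_PRESETS = {
    "germany_like": germany_like_preset,
    "norway_like": norway_like_preset,
}


def load_preset(name_or_path: str) -> RegimePreset:
    """Resolve a preset name or a YAML/JSON config file to a RegimePreset."""
    if name_or_path in _PRESETS:
        return _PRESETS[name_or_path]()
    with open(name_or_path) as fh:
        data = yaml.safe_load(fh)
    return RegimePreset.from_dict(data)


class _Draft:
    """A contact under construction (day offsets; ids assigned after sorting)."""

    __slots__ = ("day", "order", "provider", "reasons")

    def __init__(self, day: int, order: int, provider: Provider, reasons: list[str]):
        self.day = day
        self.order = order
        self.provider = provider
        self.reasons = reasons


def _interval(rng: np.random.Generator, spec: IntervalSpec) -> int:
    # Summoning intervals: normal jitter, never shorter than a week.
    return max(7, round(rng.normal(spec.mean, spec.sd)))


def _thread(
    rng: np.random.Generator,
    spec: IntervalSpec,
    horizon_days: int,
    provider: Provider,
    reason: str,
    order_start: int,
) -> list[_Draft]:
    drafts: list[_Draft] = []
    day = int(rng.uniform(0, spec.mean))
    order = order_start
    while day < horizon_days:
        drafts.append(_Draft(day, order, provider, [reason]))
        order += 1
        day += _interval(rng, spec)
    return drafts


def simulate_patient(
    profile: PatientProfile,
    regime: RegimePreset,
    horizon_days: int,
    rng: np.random.Generator,
) -> UtilizationSequence:
    """Generate one patient's utilization sequence over ``[day 0, horizon)``.

    All stochastic draws come from ``rng``.  The returned sequence is valid
    by construction (every edge points forward in time) and its attributes
    record the regime name and the chronic flag.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    regime.validate()
    pid = profile.patient_id
    gp = Provider(f"{pid}-gp", ProviderLevel.GP, "general practice")
    acute_level = (
        ProviderLevel.HOSPITAL_OUTPATIENT
        if regime.gatekeeping
        else ProviderLevel.AMBULATORY_SPECIALIST
    )
    drafts: list[_Draft] = []
    followup_pairs: list[tuple[_Draft, _Draft]] = []
    referral_pairs: list[tuple[_Draft, _Draft]] = []
    order = 0

    gp_monitor: list[_Draft] = []
    if profile.chronic:
        gp_monitor = _thread(
            rng,
            regime.gp_followup_interval_days,
            horizon_days,
            gp,
            "chronic-monitoring",
            order,
        )
        order += len(gp_monitor)
        drafts.extend(gp_monitor)
        for a, b in zip(gp_monitor, gp_monitor[1:]):
            if rng.random() < regime.p_gp_followup:
                followup_pairs.append((a, b))
        for k in range(regime.n_regular_specialists_chronic):
            specialist = Provider(
                f"{pid}-sp{k}",
                ProviderLevel.AMBULATORY_SPECIALIST,
                _SPECIALTIES[k % len(_SPECIALTIES)],
            )
            chain = _thread(
                rng,
                regime.specialist_followup_interval_days,
                horizon_days,
                specialist,
                "specialist-monitoring",
                order,
            )
            order += len(chain)
            drafts.extend(chain)
            followup_pairs.extend(zip(chain, chain[1:]))

    n_acute = rng.poisson(regime.lambda_acute_per_year * horizon_days / 365)
    acute_days = sorted(int(d) for d in rng.uniform(0, horizon_days, size=n_acute))
    n_acute_specialists = 0
    for day in acute_days:
        if not profile.chronic and rng.random() >= regime.p_acute_nonchronic_gp:
            continue  # self-care; no contact generated
        if profile.chronic:
            upcoming = next((m for m in gp_monitor if day <= m.day <= day + 7), None)
            if upcoming is not None:
                upcoming.reasons.append("acute")
                continue
        needs_specialist = rng.random() < regime.p_acute_specialist_need
        if not needs_specialist:
            drafts.append(_Draft(day, order, gp, ["acute"]))
            order += 1
            continue
        direct = rng.random() < regime.p_direct_specialist
        specialist = Provider(
            f"{pid}-asp{n_acute_specialists}", acute_level, "specialist care"
        )
        n_acute_specialists += 1
        if direct:
            drafts.append(_Draft(day, order, specialist, ["acute-specialist"]))
            order += 1
            continue
        gp_visit = _Draft(day, order, gp, ["acute"])
        order += 1
        drafts.append(gp_visit)
        referred_day = day + int(rng.uniform(7, 29))
        if referred_day < horizon_days:
            spec_visit = _Draft(referred_day, order, specialist, ["referred"])
            order += 1
            drafts.append(spec_visit)
            if rng.random() < regime.p_referral_info:
                referral_pairs.append((gp_visit, spec_visit))

    if not drafts:
        drafts.append(_Draft(int(rng.uniform(0, horizon_days)), order, gp, ["index"]))

    drafts.sort(key=lambda d: (d.day, d.order))
    ids = {id(d): f"c{i:04d}" for i, d in enumerate(drafts)}
    contacts = [
        Contact(
            contact_id=ids[id(d)],
            patient_id=pid,
            timestamp=EPOCH + datetime.timedelta(days=d.day),
            provider=d.provider,
            reasons=d.reasons,
        )
        for d in drafts
    ]

    edges = [
        InfoEdge(ids[id(a)], ids[id(b)], EdgeType.FOLLOWUP) for a, b in followup_pairs
    ] + [
        InfoEdge(ids[id(a)], ids[id(b)], EdgeType.REFERRAL) for a, b in referral_pairs
    ]
    # Reports back: specialist -> next GP contact on a strictly later day.
    gp_drafts = [d for d in drafts if d.provider.level is ProviderLevel.GP]
    for d in drafts:
        if d.provider.level is ProviderLevel.GP:
            continue
        if rng.random() < regime.p_report_back:
            target = next((g for g in gp_drafts if g.day > d.day), None)
            if target is None:
                logger.debug(
                    "patient %s: report from day %d dropped (no later GP contact)",
                    pid,
                    d.day,
                )
                continue
            edges.append(InfoEdge(ids[id(d)], ids[id(target)], EdgeType.REPORT))

    edges.sort(key=lambda e: (e.src_contact_id, e.dst_contact_id, e.edge_type.value))
    seq = build_sequence(pid, contacts, edges)
    seq.attributes = {
        "regime": regime.name,
        "chronic": profile.chronic,
        **profile.covariates,
    }
    return seq


def simulate_cohort(config: CohortConfig) -> list[UtilizationSequence]:
    """Simulate a cohort: one independent patient substream per index.

    Chronic flags are Bernoulli(``chronic_fraction``) draws from each
    patient's own substream, so the same seed always reproduces the same
    event log regardless of how the cohort is post-processed.
    """
    config.validate()
    sequences = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        chronic = bool(rng.random() < config.chronic_fraction)
        profile = PatientProfile(patient_id=f"p{i:05d}", chronic=chronic)
        sequences.append(
            simulate_patient(profile, config.regime, config.horizon_days, rng)
        )
    return sequences
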