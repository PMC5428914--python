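"""Core domain types for health-care utilization sequences.

A patient's utilization is represented as a *sequence*: the time-ordered set of
patient-provider contacts (nodes) together with typed information-flow links
between them (edges: referral, medical report, follow-up appointment).  Because
every edge must point forward in time, the resulting graph is a directed
acyclic graph; continuity and thread structure are then well-defined graph
quantities (see :mod:`careseq.measures`).

Temporal order is the total order ``(timestamp, contact_id)``: same-day
contacts are allowed (routine data routinely contains a GP and a specialist
visit on the same day) and an edge between same-day contacts is legal iff the
source precedes the destination in this order.  Time resolution is the
calendar day (ISO-8601 dates at every boundary).
"""

from __future__ import annotations

import datetime
import enum
import graphlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ProviderLevel",
    "EdgeType",
    "Provider",
    "Contact",
    "InfoEdge",
    "UtilizationSequence",
    "TraditionalMeasures",
    "Violation",
    "SequenceValidationError",
    "build_sequence",
    "validate_sequence",
    "to_traditional_measures",
]


class ProviderLevel(enum.Enum):
    """Level of a health-care provider: the vertical axis of a sequence plot.

    ``rank`` gives a distinct total ordering used for plotting and graph
    export; it carries no clinical meaning beyond "distance" from primary
    care.
    """

    GP = "GP"
    ALLIED_HEALTH = "ALLIED_HEALTH"
    AMBULATORY_SPECIALIST = "AMBULATORY_SPECIALIST"
    HOSPITAL_OUTPATIENT = "HOSPITAL_OUTPATIENT"
    HOSPITAL_INPATIENT = "HOSPITAL_INPATIENT"
    OTHER = "OTHER"

    @property
    def rank(self) -> int:
        return _LEVEL_RANKS[self]


_LEVEL_RANKS: dict[ProviderLevel, int] = {
    ProviderLevel.GP: 0,
    ProviderLevel.ALLIED_HEALTH: 1,
    ProviderLevel.AMBULATORY_SPECIALIST: 2,
    ProviderLevel.HOSPITAL_OUTPATIENT: 3,
    ProviderLevel.HOSPITAL_INPATIENT: 4,
    ProviderLevel.OTHER: 5,
}


class EdgeType(enum.Enum):
    """Kind of information flowing between two contacts.

    REFERRAL: the earlier contact refers the patient onward (letter or form).
    REPORT: findings reported back, e.g. from a specialist to the next GP
    contact.
    FOLLOWUP: a follow-up appointment made at the earlier contact and realized
    at the later one ("summoning"); directed from the contact at which the
    appointment was made to the realized follow-up, so all three kinds are
    uniformly time-forward.
    """

    REFERRAL = "REFERRAL"
    REPORT = "REPORT"
    FOLLOWUP = "FOLLOWUP"


@dataclass(frozen=True)
class Provider:
    provider_id: str
    level: ProviderLevel
    specialty: str = ""


@dataclass
class Contact:
    """One patient-provider encounter: a node of the sequence graph.

    ``reasons`` may hold zero or more free-text reason-for-encounter labels;
    encounters often have several "collected" reasons or none at all.  The
    list is carried but never interpreted.
    """

    contact_id: str
    patient_id: str
    timestamp: datetime.date
    provider: Provider
    reasons: list[str] = field(default_factory=list)

    @property
    def sort_key(self) -> tuple[datetime.date, str]:
        return (self.timestamp, self.contact_id)


@dataclass(frozen=True)
class InfoEdge:
    """A typed, time-forward information link between two contacts."""

    src_contact_id: str
    dst_contact_id: str
    edge_type: EdgeType


@dataclass
class UtilizationSequence:
    """One patient's contacts plus information edges: a validated DAG.

    ``contacts`` is sorted by ``(timestamp, contact_id)``.  ``attributes``
    carries patient covariates (chronic flag, regime label, ...) used for
    population-level stratification.
    """

    patient_id: str
    contacts: list[Contact]
    edges: list[InfoEdge]
    attributes: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.contacts)

    def contact_positions(self) -> dict[str, int]:
        """Position of each contact in the temporal total order."""
        return {c.contact_id: i for i, c in enumerate(self.contacts)}

    def to_networkx(self) -> nx.MultiDiGraph:
        """The sequence as an attributed directed multigraph.

        Parallel edges of different types between the same contact pair are
        preserved.  Node attributes carry the two plot dimensions (timestamp
        and provider-level rank).
        """
        g = nx.MultiDiGraph(patient_id=self.patient_id)
        for c in self.contacts:
            g.add_node(
                c.contact_id,
                timestamp=c.timestamp.isoformat(),
                provider_id=c.provider.provider_id,
                provider_level=c.provider.level.value,
                level_rank=c.provider.level.rank,
                specialty=c.provider.specialty,
                reasons=";".join(c.reasons),
            )
        for e in self.edges:
            g.add_edge(e.src_contact_id, e.dst_contact_id, edge_type=e.edge_type.value)
        return g


@dataclass
class TraditionalMeasures:
    """The traditional reduction of a sequence: counts and used/not-used flags.

    Visit counts per window and binary used-a-level indicators can be deduced
    directly from a sequence; they discard the edge structure entirely.
    """

    window: tuple[datetime.date, datetime.date]
    visit_count_total: int
    visit_count_by_level: dict[ProviderLevel, int]
    used_by_level: dict[ProviderLevel, bool]


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_sequence`."""

    invariant: str
    offender: str
    message: str


class SequenceValidationError(ValueError):
    """Raised by :func:`build_sequence` on invalid input; carries violations."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            "invalid utilization sequence: "
            + "; ".join(v.message for v in violations)
        )


def _edge_violations(
    patient_id: str, contacts: list[Contact], edges: Iterable[InfoEdge]
) -> list[Violation]:
    pos = {c.contact_id: i for i, c in enumerate(contacts)}
    out: list[Violation] = []
    for e in edges:
        name = f"{e.src_contact_id}->{e.dst_contact_id}[{e.edge_type.value}]"
        if e.src_contact_id == e.dst_contact_id:
            out.append(
                Violation("distinct-endpoints", name, f"edge {name} is a self-loop")
            )
            continue
        missing = [cid for cid in (e.src_contact_id, e.dst_contact_id) if cid not in pos]
        if missing:
            out.append(
                Violation(
                    "resolvable-endpoints",
                    name,
                    f"edge {name} references unknown contact(s) {missing} "
                    f"of patient {patient_id}",
                )
            )
            continue
        if pos[e.src_contact_id] >= pos[e.dst_contact_id]:
            out.append(
                Violation(
                    "time-forward",
                    name,
                    f"edge {name} does not point forward in the "
                    "(timestamp, contact_id) order",
                )
            )
    return out


def build_sequence(
    patient_id: str,
    contacts: Iterable[Contact],
    edges: Iterable[InfoEdge] = (),
) -> UtilizationSequence:
    """Construct a validated utilization sequence.

    Contacts are sorted by ``(timestamp, contact_id)``; edges are preserved
    verbatim.  Acyclicity of the edge set is asserted explicitly (it follows
    from the time-forward rule over a strict total order, but is checked with
    an independent topological sort rather than taken on faith).

    Raises
    ------
    SequenceValidationError
        On an empty contact list, a foreign or duplicate contact, or an edge
        that is a self-loop, dangles, or points backward in time.  The error
        names every offending element.
    """
    contacts = list(contacts)
    edges = list(edges)
    violations: list[Violation] = []
    if not contacts:
        raise SequenceValidationError(
            [Violation("non-empty", patient_id, "sequence has no contacts")]
        )
    for c in contacts:
        if c.patient_id != patient_id:
            violations.append(
                Violation(
                    "single-patient",
                    c.contact_id,
                    f"contact {c.contact_id} belongs to patient "
                    f"{c.patient_id!r}, not {patient_id!r}",
                )
            )
    seen: set[str] = set()
    for c in contacts:
        if c.contact_id in seen:
            violations.append(
                Violation(
                    "unique-contact-id",
                    c.contact_id,
                    f"duplicate contact_id {c.contact_id!r}",
                )
            )
        seen.add(c.contact_id)
    ordered = sorted(contacts, key=lambda c: c.sort_key)
    violations.extend(_edge_violations(patient_id, ordered, edges))
    if violations:
        raise SequenceValidationError(violations)
    # Independent acyclicity assertion (graphlib raises CycleError on a cycle).
    adj: dict[str, list[str]] = {c.contact_id: [] for c in ordered}
    for e in edges:
        adj[e.dst_contact_id].append(e.src_contact_id)
    graphlib.TopologicalSorter(adj).prepare()
    return UtilizationSequence(patient_id=patient_id, contacts=ordered, edges=edges)


def validate_sequence(seq: UtilizationSequence) -> list[Violation]:
    """Check every sequence invariant; report violations instead of raising.

    Returns an empty list iff the sequence is valid: contacts non-empty,
    unique and single-patient, sorted, and the edge set a time-forward DAG
    with resolvable endpoints.
    """
    violations: list[Violation] = []
    if not seq.contacts:
        violations.append(
            Violation("non-empty", seq.patient_id, "sequence has no contacts")
        )
        return violations
    ids = [c.contact_id for c in seq.contacts]
    seen: set[str] = set()
    for cid in ids:
        if cid in seen:
            violations.append(
                Violation("unique-contact-id", cid, f"duplicate contact_id {cid!r}")
            )
        seen.add(cid)
    for c in seq.contacts:
        if c.patient_id != seq.patient_id:
            violations.append(
                Violation(
                    "single-patient",
                    c.contact_id,
                    f"contact {c.contact_id} belongs to a different patient",
                )
            )
    keys = [c.sort_key for c in seq.contacts]
    if keys != sorted(keys):
        violations.append(
            Violation(
                "sorted-contacts",
                seq.patient_id,
                "contacts are not sorted by (timestamp, contact_id)",
            )
        )
    violations.extend(_edge_violations(seq.patient_id, seq.contacts, seq.edges))
    if not violations:
        # Redundant with time-forward but asserted independently via networkx.
        if not nx.is_directed_acyclic_graph(seq.to_networkx()):
            violations.append(
                Violation("acyclic", seq.patient_id, "edge set contains a cycle")
            )
    return violations


def to_traditional_measures(
    seq: UtilizationSequence,
    window: tuple[datetime.date, datetime.date],
) -> TraditionalMeasures:
    """Reduce a sequence to visit counts and used/not-used flags.

    Counts cover contacts with timestamp in the half-open window
    ``[start, end)``.  ``used_by_level[L]`` is true iff the level-L count is
    at least 1; counts over levels sum to the total.
    """
    start, end = window
    if start > end:
        raise ValueError(f"inverted window: start {start} > end {end}")
    by_level = {level: 0 for level in ProviderLevel}
    total = 0
    for c in seq.contacts:
        if start <= c.timestamp < end:
            by_level[c.provider.level] += 1
            total += 1
    return TraditionalMeasures(
        window=(start, end),
        visit_count_total=total,
        visit_count_by_level=by_level,
        used_by_level={level: n >= 1 for level, n in by_level.items()},
    )
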