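"""Sequence-level summary measures.

Three families of measures describe a utilization sequence: the intervals
between visits, the providers involved, and the continuity of the flow of
information.  *Continuity* is the fraction of non-initial contacts connected
by at least one information edge to a temporally preceding contact; in a
time-forward DAG, "connected to some earlier node" is exactly "has at least
one incoming edge", so an in-degree scan is the exact computation, not an
approximation.  *Threads* are the weakly connected components of the graph:
strands of care only loosely (or not at all) linked to the patient's other
care, e.g. an orthopedist/physiotherapy strand alongside an unconnected
family-physician strand.
"""

from __future__ import annotations

import datetime
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import EdgeType, ProviderLevel, UtilizationSequence

__all__ = [
    "SequenceSummary",
    "SUMMARY_COLUMNS",
    "intervisit_intervals",
    "count_providers",
    "continuity_of_information",
    "information_threads",
    "summarize_sequence",
]

#: Fixed column order of the per-patient summary CSV row.  Sequence
#: attributes are appended after these, each as ``attr_<key>``, in sorted
#: key order.  Missing values serialize as empty fields.
SUMMARY_COLUMNS = [
    "patient_id",
    "n_contacts",
    "observation_days",
    "contacts_per_year",
    "mean_interval_days",
    "median_interval_days",
    "mean_interval_days_gp",
    "n_providers",
    "n_provider_levels",
    "continuity",
    "n_threads",
    "largest_thread_fraction",
    "edges_referral",
    "edges_report",
    "edges_followup",
]


@dataclass
class SequenceSummary:
    """Per-patient record of all sequence-level measures.

    ``continuity``, ``mean_interval_days``, ``median_interval_days`` and
    ``mean_interval_days_gp`` are ``None`` (missing) when fewer than two
    qualifying contacts exist; a single contact has no preceding contact, so
    reporting a continuity of 0 or 1 for it would be meaningless either way.
    """

    patient_id: str
    n_contacts: int
    observation_days: int
    contacts_per_year: float
    mean_interval_days: Optional[float]
    median_interval_days: Optional[float]
    mean_interval_days_gp: Optional[float]
    n_providers: int
    n_provider_levels: int
    continuity: Optional[float]
    n_threads: int
    largest_thread_fraction: float
    edge_counts: dict[EdgeType, int]
    attributes: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten to one CSV-ready record (fixed columns, then attr_*)."""
        row = {
            "patient_id": self.patient_id,
            "n_contacts": self.n_contacts,
            "observation_days": self.observation_days,
            "contacts_per_year": self.contacts_per_year,
            "mean_interval_days": self.mean_interval_days,
            "median_interval_days": self.median_interval_days,
            "mean_interval_days_gp": self.mean_interval_days_gp,
            "n_providers": self.n_providers,
            "n_provider_levels": self.n_provider_levels,
            "continuity": self.continuity,
            "n_threads": self.n_threads,
            "largest_thread_fraction": self.largest_thread_fraction,
            "edges_referral": self.edge_counts.get(EdgeType.REFERRAL, 0),
            "edges_report": self.edge_counts.get(EdgeType.REPORT, 0),
            "edges_followup": self.edge_counts.get(EdgeType.FOLLOWUP, 0),
        }
        for key in sorted(self.attributes):
            row[f"attr_{key}"] = self.attributes[key]
        return row


def intervisit_intervals(
    seq: UtilizationSequence,
    level_filter: Optional[ProviderLevel] = None,
) -> list[int]:
    """Day gaps between consecutive contacts, optionally at one provider level.

    Returns the n-1 gaps between the n qualifying contacts in temporal order
    (all >= 0; same-day contacts yield 0), or an empty list if fewer than two
    contacts qualify.  Unfiltered, the gaps sum to the first-to-last timestamp
    difference.
    """
    contacts = [
        c
        for c in seq.contacts
        if level_filter is None or c.provider.level == level_filter
    ]
    return [
        (b.timestamp - a.timestamp).days
        for a, b in zip(contacts, contacts[1:])
    ]


def count_providers(seq: UtilizationSequence) -> tuple[int, int]:
    """Distinct providers and distinct provider levels involved."""
    providers = {c.provider.provider_id for c in seq.contacts}
    levels = {c.provider.level for c in seq.contacts}
    return len(providers), len(levels)


def continuity_of_information(seq: UtilizationSequence) -> Optional[float]:
    """Fraction of non-initial contacts informed by a preceding contact.

    A contact counts as informed iff at least one information edge (of any
    type; parallel edges count once) arrives at it.  The denominator is
    n - 1: the initial contact can have no predecessor and is excluded.
    Returns ``None`` for a single-contact sequence.
    """
    n = len(seq.contacts)
    if n < 2:
        return None
    informed = {e.dst_contact_id for e in seq.edges}
    return len(informed) / (n - 1)


def information_threads(seq: UtilizationSequence) -> list[list[str]]:
    """Partition contacts into threads: weakly connected components.

    Edge direction and type are ignored — a referral without a report back
    still ties two contacts into one thread of care.  Isolated contacts form
    singleton threads.  Threads are returned ordered by their earliest
    contact, members in temporal order, so output is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(c.contact_id for c in seq.contacts)
    g.add_edges_from((e.src_contact_id, e.dst_contact_id) for e in seq.edges)
    pos = seq.contact_positions()
    threads = [
        sorted(component, key=pos.__getitem__)
        for component in nx.connected_components(g)
    ]
    threads.sort(key=lambda t: pos[t[0]])
    return threads


def _mean(values: list) -> Optional[float]:
    return sum(values) / len(values) if values else None


def _median(values: list) -> Optional[float]:
    if not values:
        return None
    s = sorted(values)
    mid = len(s) // 2
    return float(s[mid]) if len(s) % 2 else (s[mid - 1] + s[mid]) / 2


def _window_subsequence(
    seq: UtilizationSequence,
    window: tuple[datetime.date, datetime.date],
) -> UtilizationSequence:
    start, end = window
    contacts = [c for c in seq.contacts if start <= c.timestamp < end]
    kept = {c.contact_id for c in contacts}
    edges = [
        e for e in seq.edges if e.src_contact_id in kept and e.dst_contact_id in kept
    ]
    return UtilizationSequence(
        patient_id=seq.patient_id,
        contacts=contacts,
        edges=edges,
        attributes=seq.attributes,
    )


def summarize_sequence(
    seq: UtilizationSequence,
    window: Optional[tuple[datetime.date, datetime.date]] = None,
) -> SequenceSummary:
    """Compute every sequence-level measure over an observation window.

    The window is half-open ``[start, end)`` and defaults to
    ``[first contact, last contact + 1 day)``, so a sequence spanning s days
    has ``observation_days = s + 1`` and an annualized contact rate of
    ``n_contacts * 365 / observation_days``.  With an explicit window, only
    contacts inside it — and edges with both endpoints inside — enter the
    measures.

    Raises
    ------
    ValueError
        On an inverted window, or a window containing no contacts (a summary
        of nothing has no defined measures).
    """
    if window is None:
        window = (
            seq.contacts[0].timestamp,
            seq.contacts[-1].timestamp + datetime.timedelta(days=1),
        )
    start, end = window
    if start > end:
        raise ValueError(f"inverted window: start {start} > end {end}")
    sub = _window_subsequence(seq, window)
    if not sub.contacts:
        raise ValueError(
            f"window [{start}, {end}) contains no contacts of patient "
            f"{seq.patient_id}"
        )
    n = len(sub.contacts)
    observation_days = (end - start).days
    intervals = intervisit_intervals(sub)
    gp_intervals = intervisit_intervals(sub, level_filter=ProviderLevel.GP)
    n_providers, n_levels = count_providers(sub)
    threads = information_threads(sub)
    edge_counts = Counter(e.edge_type for e in sub.edges)
    return SequenceSummary(
        patient_id=seq.patient_id,
        n_contacts=n,
        observation_days=observation_days,
        contacts_per_year=n * 365 / observation_days,
        mean_interval_days=_mean(intervals),
        median_interval_days=_median(intervals),
        mean_interval_days_gp=_mean(gp_intervals),
        n_providers=n_providers,
        n_provider_levels=n_levels,
        continuity=continuity_of_information(sub),
        n_threads=len(threads),
        largest_thread_fraction=max(len(t) for t in threads) / n,
        edge_counts={t: edge_counts.get(t, 0) for t in EdgeType},
        attributes=dict(seq.attributes),
    )
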