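"""Event-table readers/writers and graph exports.

This is the boundary where routine-data extracts enter the model.  Input is
a flat two-table encoding of nodes and edges:

contacts table (CSV, UTF-8, comma, header required)::

    patient_id,contact_id,date,provider_id,provider_level,specialty,reasons

edges table::

    patient_id,src_contact_id,dst_contact_id,edge_type

``date`` is ISO-8601; ``reasons`` is semicolon-joined and may be empty;
``provider_level`` is one of the ProviderLevel names (an empty level maps to
OTHER with a logged warning); ``edge_type`` is REFERRAL, REPORT or FOLLOWUP.
Parsing is strict: malformed dates, unknown edge types, unknown levels and
dangling contact references are collected and reported with their CSV line
numbers rather than silently coerced or dropped — routine-data QA needs that
visibility.

Writers emit stable orderings (patient_id, then temporal order) so identical
cohorts produce byte-identical files.
"""

from __future__ import annotations

import datetime
import json
import logging
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .measures import SUMMARY_COLUMNS, SequenceSummary
from .model import (
    Contact,
    EdgeType,
    InfoEdge,
    Provider,
    ProviderLevel,
    SequenceValidationError,
    UtilizationSequence,
    build_sequence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CONTACTS_COLUMNS",
    "EDGES_COLUMNS",
    "SchemaError",
    "read_event_tables",
    "write_event_tables",
    "write_attributes",
    "read_attributes",
    "write_summaries",
    "read_summaries",
    "export_graph",
]

CONTACTS_COLUMNS = [
    "patient_id",
    "contact_id",
    "date",
    "provider_id",
    "provider_level",
    "specialty",
    "reasons",
]
EDGES_COLUMNS = ["patient_id", "src_contact_id", "dst_contact_id", "edge_type"]


class SchemaError(ValueError):
    """A structural problem in an input table; carries per-row messages."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(
            [f"{path}: missing required column(s) {missing}; found {list(df.columns)}"]
        )
    return df


def read_event_tables(
    contacts_path, edges_path
) -> dict[str, UtilizationSequence]:
    """Read and validate event tables into one sequence per patient.

    Raises
    ------
    SchemaError
        Listing every malformed row with its CSV line number (the header is
        line 1), or any missing required column.
    """
    contacts_df = _read_table(contacts_path, CONTACTS_COLUMNS)
    edges_df = _read_table(edges_path, EDGES_COLUMNS)
    problems: list[str] = []

    contacts_by_patient: dict[str, list[Contact]] = {}
    known: set[tuple[str, str]] = set()
    for i, row in enumerate(contacts_df.itertuples(index=False)):
        line = i + 2
        try:
            timestamp = datetime.date.fromisoformat(row.date)
        except ValueError:
            problems.append(
                f"{contacts_path} line {line}: malformed date {row.date!r}"
            )
            continue
        level_name = row.provider_level
        if level_name == "":
            logger.warning(
                "%s line %d: missing provider_level, mapping to OTHER",
                contacts_path,
                line,
            )
            level = ProviderLevel.OTHER
        else:
            try:
                level = ProviderLevel[level_name]
            except KeyError:
                problems.append(
                    f"{contacts_path} line {line}: unknown provider_level "
                    f"{level_name!r}"
                )
                continue
        key = (row.patient_id, row.contact_id)
        if key in known:
            problems.append(
                f"{contacts_path} line {line}: duplicate contact_id "
                f"{row.contact_id!r} for patient {row.patient_id!r}"
            )
            continue
        known.add(key)
        contacts_by_patient.setdefault(row.patient_id, []).append(
            Contact(
                contact_id=row.contact_id,
                patient_id=row.patient_id,
                timestamp=timestamp,
                provider=Provider(row.provider_id, level, row.specialty),
                reasons=[r for r in row.reasons.split(";") if r],
            )
        )

    edges_by_patient: dict[str, list[InfoEdge]] = {}
    for i, row in enumerate(edges_df.itertuples(index=False)):
        line = i + 2
        try:
            edge_type = EdgeType[row.edge_type]
        except KeyError:
            problems.append(
                f"{edges_path} line {line}: unknown edge_type {row.edge_type!r}"
            )
            continue
        dangling = [
            cid
            for cid in (row.src_contact_id, row.dst_contact_id)
            if (row.patient_id, cid) not in known
        ]
        if dangling:
            problems.append(
                f"{edges_path} line {line}: edge references unknown "
                f"contact(s) {dangling} of patient {row.patient_id!r}"
            )
            continue
        edges_by_patient.setdefault(row.patient_id, []).append(
            InfoEdge(row.src_contact_id, row.dst_contact_id, edge_type)
        )

    if problems:
        raise SchemaError(problems)

    sequences: dict[str, UtilizationSequence] = {}
    for patient_id in sorted(contacts_by_patient):
        try:
            sequences[patient_id] = build_sequence(
                patient_id,
                contacts_by_patient[patient_id],
                edges_by_patient.get(patient_id, []),
            )
        except SequenceValidationError as err:
            problems.extend(f"patient {patient_id}: {v.message}" for v in err.violations)
    if problems:
        raise SchemaError(problems)
    return sequences


def _canonical_edges(seq: UtilizationSequence) -> list[InfoEdge]:
    pos = seq.contact_positions()
    return sorted(
        seq.edges,
        key=lambda e: (pos[e.src_contact_id], pos[e.dst_contact_id], e.edge_type.value),
    )


def write_event_tables(
    sequences: Sequence[UtilizationSequence] | Mapping[str, UtilizationSequence],
    contacts_path,
    edges_path,
) -> None:
    """Write sequences to the two-table schema with stable ordering.

    Patients are ordered by id, contacts temporally, edges by (source
    position, destination position, type), so identical cohorts produce
    byte-identical files.  An empty cohort yields header-only files.
    """
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    ordered = sorted(sequences, key=lambda s: s.patient_id)
    contact_rows = [
        {
            "patient_id": seq.patient_id,
            "contact_id": c.contact_id,
            "date": c.timestamp.isoformat(),
            "provider_id": c.provider.provider_id,
            "provider_level": c.provider.level.name,
            "specialty": c.provider.specialty,
            "reasons": ";".join(c.reasons),
        }
        for seq in ordered
        for c in seq.contacts
    ]
    edge_rows = [
        {
            "patient_id": seq.patient_id,
            "src_contact_id": e.src_contact_id,
            "dst_contact_id": e.dst_contact_id,
            "edge_type": e.edge_type.name,
        }
        for seq in ordered
        for e in _canonical_edges(seq)
    ]
    pd.DataFrame(contact_rows, columns=CONTACTS_COLUMNS).to_csv(
        contacts_path, index=False, lineterminator="\n"
    )
    pd.DataFrame(edge_rows, columns=EDGES_COLUMNS).to_csv(
        edges_path, index=False, lineterminator="\n"
    )


def write_attributes(
    sequences: Sequence[UtilizationSequence] | Mapping[str, UtilizationSequence],
    path,
) -> None:
    """Patient covariate side-table: patient_id plus one column per attribute.

    Event tables carry only the graph itself; covariates used for
    stratification (regime label, chronic flag, ...) travel in this separate
    table and are re-attached by :func:`read_attributes`.
    """
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    ordered = sorted(sequences, key=lambda s: s.patient_id)
    keys = sorted({k for s in ordered for k in s.attributes})
    rows = [
        {"patient_id": s.patient_id, **{k: s.attributes.get(k) for k in keys}}
        for s in ordered
    ]
    pd.DataFrame(rows, columns=["patient_id"] + keys).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_attributes(path) -> dict[str, dict]:
    """Read a covariate side-table as a patient_id -> attributes mapping."""
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError([f"{path}: missing required column(s) ['patient_id']"])
    out: dict[str, dict] = {}
    for row in df.to_dict(orient="records"):
        pid = str(row.pop("patient_id"))
        out[pid] = row
    return out


def write_summaries(summaries: Sequence[SequenceSummary], path) -> None:
    """One CSV row per patient: fixed measure columns, then attr_* columns."""
    rows = [s.to_row() for s in summaries]
    attr_cols = sorted({k for row in rows for k in row if k.startswith("attr_")})
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS + attr_cols)
    df.to_csv(path, index=False, lineterminator="\n")


def read_summaries(path) -> pd.DataFrame:
    """Read a summaries CSV as written by :func:`write_summaries`."""
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError([f"{path}: missing required column(s) {missing}"])
    return df


def export_graph(seq: UtilizationSequence, path, format: str = "graphml") -> None:
    """Export one sequence as an attributed directed graph.

    Nodes carry the two plot dimensions (ISO timestamp, provider-level rank)
    plus provider identity; edges carry their type.  ``graphml`` output loads
    in standard graph tooling; ``json`` writes a ``{patient_id, attributes,
    nodes, edges}`` document.
    """
    g = seq.to_networkx()
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "json":
        doc = {
            "patient_id": seq.patient_id,
            "attributes": {k: v for k, v in seq.attributes.items()},
            "nodes": [
                {"contact_id": n, **attrs} for n, attrs in g.nodes(data=True)
            ],
            "edges": [
                {"src_contact_id": u, "dst_contact_id": v, **attrs}
                for u, v, attrs in g.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {format!r}; use graphml or json")
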