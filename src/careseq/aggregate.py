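"""Population-level aggregation of sequence summaries and regime comparison.

Individual summaries are pooled into per-stratum descriptive statistics
(mean, median, IQR, fraction missing) for every numeric measure.  Strata are
generic attribute keys carried on the sequences (e.g. regime, chronic flag).
Missing values — e.g. the undefined continuity of a single-contact sequence —
are excluded from the moments and counted in the missing fraction instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .measures import SUMMARY_COLUMNS, SequenceSummary

__all__ = [
    "MEASURE_COLUMNS",
    "MeasureStats",
    "PopulationSummary",
    "DataError",
    "aggregate_cohort",
    "population_frame",
    "frame_to_populations",
    "compare_regimes",
]

#: Numeric summary fields aggregated per stratum.
MEASURE_COLUMNS = [c for c in SUMMARY_COLUMNS if c != "patient_id"]

_STRATUM_SENTINEL = "__all__"


class DataError(ValueError):
    """Inconsistent stratifiers across patients."""


@dataclass
class MeasureStats:
    mean: Optional[float]
    median: Optional[float]
    iqr: Optional[float]
    fraction_missing: float


@dataclass
class PopulationSummary:
    """Descriptive statistics of one stratum of a cohort."""

    stratum: dict
    n_patients: int
    stats: dict[str, MeasureStats] = field(default_factory=dict)


def _summaries_frame(
    summaries: Union[Sequence[SequenceSummary], pd.DataFrame],
) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries.copy()
    return pd.DataFrame([s.to_row() for s in summaries])


def _stats(series: pd.Series) -> MeasureStats:
    values = pd.to_numeric(series, errors="coerce")
    present = values.dropna()
    n = len(values)
    if present.empty:
        return MeasureStats(None, None, None, 1.0 if n else 0.0)
    q1, q3 = np.percentile(present, [25, 75])
    return MeasureStats(
        mean=float(present.mean()),
        median=float(present.median()),
        iqr=float(q3 - q1),
        fraction_missing=float((n - len(present)) / n),
    )


def aggregate_cohort(
    summaries: Union[Sequence[SequenceSummary], pd.DataFrame],
    strata_keys: Sequence[str] = (),
) -> list[PopulationSummary]:
    """Aggregate per-patient summaries into per-stratum statistics.

    ``strata_keys`` name sequence attributes (``attr_<key>`` columns of the
    summaries table).  With no keys, the whole cohort forms a single
    stratum.  A stratifier present for some patients but not others is a data
    error (the offending patients are listed); patient counts over strata
    always sum to the cohort size.
    """
    df = _summaries_frame(summaries)
    if df.empty:
        return []
    group_cols = []
    for key in strata_keys:
        col = f"attr_{key}"
        if col not in df.columns:
            raise DataError(
                f"stratifier {key!r} absent from all patients "
                f"(no column {col!r})"
            )
        offenders = df.loc[df[col].isna(), "patient_id"].tolist()
        if offenders:
            raise DataError(
                f"stratifier {key!r} missing for patient(s) {offenders}"
            )
        group_cols.append(col)
    if not group_cols:
        df = df.assign(**{_STRATUM_SENTINEL: "all"})
        group_cols = [_STRATUM_SENTINEL]
    out: list[PopulationSummary] = []
    for values, group in df.groupby(group_cols, sort=True):
        if not isinstance(values, tuple):
            values = (values,)
        stratum = (
            {}
            if group_cols == [_STRATUM_SENTINEL]
            else dict(zip(strata_keys, values))
        )
        stats = {m: _stats(group[m]) for m in MEASURE_COLUMNS if m in group.columns}
        out.append(
            PopulationSummary(stratum=stratum, n_patients=len(group), stats=stats)
        )
    return out


def population_frame(populations: Sequence[PopulationSummary]) -> pd.DataFrame:
    """Tidy table: one row per (stratum, measure) with the four statistics."""
    rows = []
    for pop in populations:
        for measure, st in pop.stats.items():
            rows.append(
                {
                    **{f"stratum_{k}": v for k, v in pop.stratum.items()},
                    "n_patients": pop.n_patients,
                    "measure": measure,
                    "mean": st.mean,
                    "median": st.median,
                    "iqr": st.iqr,
                    "fraction_missing": st.fraction_missing,
                }
            )
    return pd.DataFrame(rows)


def frame_to_populations(df: pd.DataFrame) -> list[PopulationSummary]:
    """Inverse of :func:`population_frame` (used to reload aggregate CSVs)."""
    if df.empty:
        return []
    stratum_cols = [c for c in df.columns if c.startswith("stratum_")]
    out = []
    group_cols = stratum_cols if stratum_cols else lambda _: 0
    for _, group in df.groupby(group_cols, sort=True):
        first = group.iloc[0]
        stratum = {c[len("stratum_"):]: first[c] for c in stratum_cols}
        stats = {
            row["measure"]: MeasureStats(
                mean=None if pd.isna(row["mean"]) else float(row["mean"]),
                median=None if pd.isna(row["median"]) else float(row["median"]),
                iqr=None if pd.isna(row["iqr"]) else float(row["iqr"]),
                fraction_missing=float(row["fraction_missing"]),
            )
            for _, row in group.iterrows()
        }
        out.append(
            PopulationSummary(
                stratum=stratum, n_patients=int(first["n_patients"]), stats=stats
            )
        )
    return out


def _stratum_key(pop: PopulationSummary) -> tuple:
    return tuple(sorted(pop.stratum.items()))


def compare_regimes(
    pops_a: Sequence[PopulationSummary],
    pops_b: Sequence[PopulationSummary],
) -> pd.DataFrame:
    """Per-measure comparison of two aggregated populations.

    For every stratum (which must match between the two populations) and
    measure: both means, their difference ``mean_a - mean_b`` and the ratio
    ``mean_a / mean_b`` (missing when the denominator mean is 0 or
    undefined).  Orientation is A/B with A the first argument.
    """
    a_by_stratum = {_stratum_key(p): p for p in pops_a}
    b_by_stratum = {_stratum_key(p): p for p in pops_b}
    if set(a_by_stratum) != set(b_by_stratum):
        raise ValueError(
            "mismatched strata: "
            f"{sorted(set(a_by_stratum) ^ set(b_by_stratum))}"
        )
    rows = []
    for key in sorted(a_by_stratum):
        pa, pb = a_by_stratum[key], b_by_stratum[key]
        for measure in pa.stats:
            if measure not in pb.stats:
                continue
            ma, mb = pa.stats[measure].mean, pb.stats[measure].mean
            diff = ma - mb if ma is not None and mb is not None else None
            ratio = ma / mb if ma is not None and mb not in (None, 0) else None
            rows.append(
                {
                    **{f"stratum_{k}": v for k, v in pa.stratum.items()},
                    "measure": measure,
                    "mean_a": ma,
                    "mean_b": mb,
                    "diff": diff,
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)
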