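"""Technique-comparison and repeatability statistics for replicate distances.

When the same inter-landmark distance is measured several times, by several
operators, on models produced by several digitization techniques (micro-CT,
structured-light scanning, photogrammetry, sphere-of-images triangulation),
three percent statistics summarize agreement:

* difference to the reference technique (micro-CT by convention):
  ``100 * (mean(technique) - mean(reference)) / mean(reference)``
* inter-operator difference:
  ``100 * (mean(operator A) - mean(operator B)) / mean(operator B)``
* dispersion of the pooled replicates of one technique:
  ``100 * (max - min) / mean``

Per-specimen averages of the signed reference differences, and a global
absolute/cumulated summary over all specimens and operators, rank the
techniques.  A separate repeatability summary (mean, sample sd, dispersion,
95% interval ``mean ± t_{0.975,n-1} sd``) describes a long replicate series
of a single distance.

All statistics are computed at full precision; replicate tables published
rounded to 0.01 mm reproduce the derived cells to about ±0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInput, MismatchedKeys, TooFewValues

__all__ = [
    "MeasurementSeries",
    "ComparisonRow",
    "RepeatabilitySummary",
    "load_measurements",
    "load_bundled_measurements",
    "load_bundled_repeatability",
    "pct_diff_to_reference",
    "interoperator_diff",
    "dispersion",
    "build_comparison_rows",
    "aggregate_differences",
    "global_absolute_summary",
    "repeatability_summary",
]

#: column layout of a measurement CSV
MEASUREMENT_COLUMNS = (
    "specimen",
    "distance_label",
    "technique",
    "operator",
    "replicate",
    "value_mm",
)


@dataclass(frozen=True)
class MeasurementSeries:
    """Replicate distance values for one (specimen, distance, technique, operator)."""

    specimen: str
    distance_label: str
    technique: str
    operator: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise TooFewValues("a measurement series cannot be empty")
        if any(v <= 0 for v in vals):
            raise ValueError("distance values must be positive")
        object.__setattr__(self, "values", vals)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class ComparisonRow:
    """Derived statistics for one (specimen, distance, technique) cell."""

    specimen: str
    distance_label: str
    technique: str
    avg: Mapping[str, float]  # operator -> mean, mm
    diff_to_reference: Mapping[str, float]  # operator -> percent
    interoperator_diff_pct: float
    dispersion_pct: float


@dataclass(frozen=True)
class RepeatabilitySummary:
    """Distribution parameters of a long replicate series of one distance."""

    mean: float
    stdev: float
    diff_to_reference_pct: float
    dispersion_pct: float
    ci95: tuple[float, float]
    n: int


# --- input ----------------------------------------------------------------


def load_measurements(source) -> list[MeasurementSeries]:
    """Load a replicate table (CSV path or DataFrame) into series.

    Expected columns: specimen, distance_label, technique, operator,
    replicate, value_mm.
    """
    table = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise EmptyInput(f"measurement table missing columns: {missing}")
    out = []
    keys = ["specimen", "distance_label", "technique", "operator"]
    for (spec, dist, tech, op), grp in table.groupby(keys, sort=False):
        grp = grp.sort_values("replicate")
        out.append(
            MeasurementSeries(
                specimen=str(spec),
                distance_label=str(dist),
                technique=str(tech),
                operator=str(op),
                values=tuple(grp["value_mm"].astype(float)),
            )
        )
    return out


def load_bundled_measurements() -> list[MeasurementSeries]:
    """The packaged four-specimen replicate table (3 replicates x 2 operators)."""
    with resources.files(__package__).joinpath(
        "data/comparison_measurements.csv"
    ).open() as fh:
        return load_measurements(pd.read_csv(fh))


def load_bundled_repeatability() -> pd.DataFrame:
    """The packaged 20-replicate single-distance table (columns: technique,
    replicate, value_mm)."""
    with resources.files(__package__).joinpath(
        "data/repeatability_lr.csv"
    ).open() as fh:
        return pd.read_csv(fh)


# --- elementary statistics ------------------------------------------------


def pct_diff_to_reference(
    series: MeasurementSeries, reference: MeasurementSeries
) -> float:
    """Signed percent difference of means against the reference technique."""
    if (series.specimen, series.distance_label) != (
        reference.specimen,
        reference.distance_label,
    ):
        raise MismatchedKeys(
            "series and reference must describe the same specimen and distance"
        )
    return 100.0 * (series.mean - reference.mean) / reference.mean


def interoperator_diff(a: MeasurementSeries, b: MeasurementSeries) -> float:
    """Signed percent difference of operator means for one technique."""
    if (a.specimen, a.distance_label, a.technique) != (
        b.specimen,
        b.distance_label,
        b.technique,
    ):
        raise MismatchedKeys(
            "operator series must share specimen, distance and technique"
        )
    if a.operator == b.operator:
        raise MismatchedKeys("inter-operator difference needs two distinct operators")
    return 100.0 * (a.mean - b.mean) / b.mean


def dispersion(values: Sequence[float]) -> float:
    """Percent spread 100 * (max - min) / mean of pooled replicates."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise TooFewValues("dispersion needs at least two values")
    return float(100.0 * (vals.max() - vals.min()) / vals.mean())


# --- table building and aggregation ---------------------------------------


def _index(series: Sequence[MeasurementSeries]):
    by_key: dict[tuple[str, str, str], dict[str, MeasurementSeries]] = {}
    for s in series:
        by_key.setdefault(
            (s.specimen, s.distance_label, s.technique), {}
        )[s.operator] = s
    return by_key


def build_comparison_rows(
    series: Sequence[MeasurementSeries], reference_technique: str = "uCT"
) -> list[ComparisonRow]:
    """Assemble per-(specimen, distance, technique) comparison rows.

    Reference differences are computed operator-by-operator against the
    same operator's reference series; the inter-operator difference uses
    the two operators in lexicographic order (A vs B); the dispersion pools
    all operators' replicates of the technique.
    """
    if not series:
        raise EmptyInput("no measurement series supplied")
    by_key = _index(series)
    rows = []
    for (spec, dist, tech), ops in by_key.items():
        ref_ops = by_key.get((spec, dist, reference_technique), {})
        avg = {op: s.mean for op, s in sorted(ops.items())}
        diffs = {
            op: pct_diff_to_reference(s, ref_ops[op])
            for op, s in sorted(ops.items())
            if op in ref_ops
        }
        op_names = sorted(ops)
        inter = (
            interoperator_diff(ops[op_names[0]], ops[op_names[1]])
            if len(op_names) >= 2
            else 0.0
        )
        pooled = [v for op in op_names for v in ops[op].values]
        rows.append(
            ComparisonRow(
                specimen=spec,
                distance_label=dist,
                technique=tech,
                avg=avg,
                diff_to_reference=diffs,
                interoperator_diff_pct=inter,
                dispersion_pct=dispersion(pooled),
            )
        )
    return rows


def aggregate_differences(
    rows: Sequence[ComparisonRow], technique: str
) -> tuple[float, float, float]:
    """Per-operator means of the signed reference differences of one specimen.

    Returns ``(avg_A, avg_B, avg_AB)`` where the operator labels follow
    lexicographic order and ``avg_AB`` is the mean of the two operator
    averages.  All rows must belong to one specimen.
    """
    rows = [r for r in rows if r.technique == technique]
    if not rows:
        raise EmptyInput(f"no rows for technique {technique!r}")
    if len({r.specimen for r in rows}) != 1:
        raise EmptyInput("aggregate_differences expects rows of a single specimen")
    operators = sorted({op for r in rows for op in r.diff_to_reference})
    if len(operators) != 2:
        raise EmptyInput(f"expected two operators, found {operators}")
    means = [
        float(np.mean([r.diff_to_reference[op] for r in rows])) for op in operators
    ]
    return means[0], means[1], float(np.mean(means))


def global_absolute_summary(
    rows: Sequence[ComparisonRow], technique: str
) -> tuple[float, float]:
    """Absolute-average and cumulated reference differences for one technique.

    Sums |percent difference| over every (specimen, distance, operator)
    cell of the technique across all specimens; the absolute average is
    that cumulated sum divided by the number of cells.
    """
    diffs = [
        abs(d)
        for r in rows
        if r.technique == technique
        for d in r.diff_to_reference.values()
    ]
    if not diffs:
        raise EmptyInput(f"no reference differences for technique {technique!r}")
    cumulated = float(np.sum(diffs))
    return cumulated / len(diffs), cumulated


def repeatability_summary(
    values: Sequence[float], reference_values: Sequence[float]
) -> RepeatabilitySummary:
    """Distribution parameters of a long replicate series.

    Mean, sample standard deviation (n-1), signed percent difference of the
    mean against the reference series' mean, pooled (max-min)/mean
    dispersion, and a 95% interval ``mean ± t_{0.975, n-1} * sd`` sized to
    cover individual repeat measurements (a prediction-style band, not a
    standard error of the mean).
    """
    vals = np.asarray(list(values), dtype=float)
    ref = np.asarray(list(reference_values), dtype=float)
    if vals.size < 2 or ref.size < 1:
        raise TooFewValues("repeatability needs >= 2 values and a reference")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    half = float(sps.t.ppf(0.975, vals.size - 1)) * sd
    return RepeatabilitySummary(
        mean=mean,
        stdev=sd,
        diff_to_reference_pct=100.0 * (mean - float(ref.mean())) / float(ref.mean()),
        dispersion_pct=dispersion(vals),
        ci95=(mean - half, mean + half),
        n=int(vals.size),
    )
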