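"""Replicate aggregation, significance tests, and the healing time course.

Densities from replicate wounds are summarized as mean +- SD (sample SD,
n-1 denominator; undefined and reported as missing for a single replicate).
Group comparisons use the classical unpaired two-tailed Student t-test with
pooled variance (alpha = 0.05); no multiple-testing correction is applied —
reports carry raw p-values and say so. The link between re-innervation and
wound closure is summarized by an ordinary least-squares fit of per-day mean
whole-wound density against per-day mean re-epithelialization percent, with
the coefficient of determination R^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .imgio import DensityRecord

__all__ = [
    "GroupSummary",
    "TTestResult",
    "CorrelationResult",
    "ReepiMeasurement",
    "summarize",
    "t_test",
    "regress_r2",
    "reepi_percent",
    "read_reepi_table",
    "write_reepi_table",
    "timecourse_report",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    day: int
    region: str
    layer: str
    n: int
    mean: float
    sd: float | None  # None when n == 1 (sample SD undefined)


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    dof: int
    p_value: float
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class ReepiMeasurement:
    """Re-epithelialization of one wound: tongue lengths vs total length."""

    sample_id: str
    day: int
    tongue_lengths: tuple[float, ...]
    total_wound_length: float
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_wound_length <= 0:
            raise ValidationError("total_wound_length must be positive")
        if any(t < 0 for t in self.tongue_lengths):
            raise ValidationError("tongue lengths must be >= 0")
        pct = 100.0 * sum(self.tongue_lengths) / self.total_wound_length
        if pct > 100.0:
            logger.warning(
                "re-epithelialization %.1f%% exceeds 100%% for %s; capped",
                pct,
                self.sample_id,
            )
            pct = 100.0
        object.__setattr__(self, "percent", pct)


def reepi_percent(
    sample_id: str,
    day: int,
    tongue_lengths: Sequence[float],
    total_wound_length: float,
) -> ReepiMeasurement:
    """Percent wound closure: combined epithelial tongue length over total."""
    return ReepiMeasurement(
        sample_id=sample_id,
        day=day,
        tongue_lengths=tuple(float(t) for t in tongue_lengths),
        total_wound_length=float(total_wound_length),
    )


def summarize(records: Sequence[DensityRecord]) -> list[GroupSummary]:
    """Mean +- SD of replicate densities per (day, region, layer) group."""
    if not records:
        raise ValidationError("records must be non-empty")
    frame = pd.DataFrame([vars(r) for r in records])
    out = []
    for (day, region, layer), grp in frame.groupby(["day", "region", "layer"], sort=True):
        values = grp["density"].to_numpy()
        sd = float(values.std(ddof=1)) if values.size > 1 else None
        out.append(
            GroupSummary(
                day=int(day),
                region=str(region),
                layer=str(layer),
                n=int(values.size),
                mean=float(values.mean()),
                sd=sd,
            )
        )
    return out


def t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Unpaired two-tailed Student t-test with pooled variance.

    Degrees of freedom are n_a + n_b - 2. When both groups have zero
    variance and equal means the statistic is defined as 0 with p = 1; with
    unequal means the difference is infinitely many pooled SDs, reported as
    an infinite statistic with p = 0.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("group values must be finite")
    dof = int(a.size + b.size - 2)
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / dof
    if pooled == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, dof, 1.0, False)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t, dof, 0.0, True)
    res = sps.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    return TTestResult(float(res.statistic), dof, p, p < ALPHA)


def regress_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Ordinary least-squares line y = slope*x + intercept with R^2."""
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.size != ya.size:
        raise ValidationError("x and y must have equal length")
    if xa.size < 3:
        raise ValidationError("need at least 3 points for a regression")
    if np.ptp(xa) == 0.0:
        raise ValidationError("x is constant; slope undefined")
    if np.ptp(ya) == 0.0:
        logger.warning("constant response: no explainable variance, R^2 = 0")
        return CorrelationResult(0.0, float(ya[0]), 0.0, int(xa.size))
    fit = sps.linregress(xa, ya)
    return CorrelationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=int(xa.size),
    )


_REEPI_COLUMNS = ["sample_id", "day", "tongue_length_1", "tongue_length_2",
                  "total_wound_length"]


def write_reepi_table(measurements: Sequence[ReepiMeasurement], path) -> None:
    if not measurements:
        raise ValidationError("measurements must be non-empty")
    rows = []
    for m in measurements:
        tongues = list(m.tongue_lengths) + [0.0, 0.0]
        rows.append(
            {
                "sample_id": m.sample_id,
                "day": m.day,
                "tongue_length_1": tongues[0],
                "tongue_length_2": tongues[1],
                "total_wound_length": m.total_wound_length,
            }
        )
    pd.DataFrame(rows, columns=_REEPI_COLUMNS).to_csv(path, index=False)


def read_reepi_table(path) -> list[ReepiMeasurement]:
    frame = pd.read_csv(path, comment="#")
    missing = set(_REEPI_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: re-epi table missing columns {sorted(missing)}")
    return [
        reepi_percent(
            str(row.sample_id),
            int(row.day),
            [float(row.tongue_length_1), float(row.tongue_length_2)],
            float(row.total_wound_length),
        )
        for row in frame.itertuples(index=False)
    ]


GroupKey = tuple[int, str, str]  # (day, region, layer)


def _group_values(records: Sequence[DensityRecord], key: GroupKey) -> list[float]:
    day, region, layer = key
    return [
        r.density
        for r in records
        if r.day == day and r.region == region and r.layer == layer
    ]


def _fill_missing_epidermis(summaries: list[GroupSummary]) -> list[GroupSummary]:
    """Report absent epithelium as zero density (0.0 +- 0.0).

    Early-timepoint wounds have no epidermis over the bed/center, so no
    epidermis record exists there; the time-course table still reports the
    group, as a zero, to keep the day x region x layer grid complete.
    """
    have = {(s.day, s.region, s.layer) for s in summaries}
    filled = list(summaries)
    for s in summaries:
        if s.layer == "dermis" and (s.day, s.region, "epidermis") not in have:
            filled.append(
                GroupSummary(day=s.day, region=s.region, layer="epidermis",
                             n=s.n, mean=0.0, sd=0.0 if s.n > 1 else None)
            )
    filled.sort(key=lambda s: (s.day, s.region, s.layer))
    return filled


def timecourse_report(
    records: Sequence[DensityRecord],
    reepi: Sequence[ReepiMeasurement],
    comparisons: Sequence[tuple[GroupKey, GroupKey]] = (),
    correlation_region: str = "wound_bed",
) -> dict:
    """Assemble the full time-course report.

    Emits per-group mean +- SD, the requested pairwise t-tests, and the OLS
    R^2 of per-day mean whole-wound density against per-day mean
    re-epithelialization percent (days present in both inputs; at least 3
    required).
    """
    if not records:
        raise ValidationError("records must be non-empty")
    summaries = _fill_missing_epidermis(summarize(records))

    tests = []
    for key_a, key_b in comparisons:
        values_a = _group_values(records, key_a)
        values_b = _group_values(records, key_b)
        result = t_test(values_a, values_b)
        tests.append({"group_a": list(key_a), "group_b": list(key_b),
                      **vars(result)})

    density_days = {
        s.day: s.mean
        for s in summaries
        if s.region == correlation_region and s.layer == "whole"
    }
    reepi_days: dict[int, list[float]] = {}
    for m in reepi:
        reepi_days.setdefault(m.day, []).append(m.percent)
    shared = sorted(set(density_days) & set(reepi_days))
    if len(shared) < 3:
        raise ValidationError(
            f"need >= 3 overlapping days for the correlation, got {shared}"
        )
    x = [density_days[d] for d in shared]
    y = [float(np.mean(reepi_days[d])) for d in shared]
    corr = regress_r2(x, y)

    return {
        "groups": [vars(s) for s in summaries],
        "t_tests": tests,
        "correlation": {**vars(corr), "days": shared,
                        "x_density": x, "y_reepi_percent": y},
        "note": (
            "raw p-values from unpaired two-tailed pooled-variance Student "
            "t-tests; no multiple-testing correction applied"
        ),
    }
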