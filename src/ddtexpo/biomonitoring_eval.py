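"""Biomonitoring summaries and model-vs-measurement evaluation.

Inputs are study-level biomonitoring records: year-stamped lipid-normalized
ΣDDT group averages and, where reported, the p,p′-DDE to p,p′-DDT ratio.
The ratio separates fresh exposure (low ratio — technical DDT is mostly
p,p′-DDT) from weathered/historical exposure (high ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BiomonitoringRecord",
    "DeclineRate",
    "ratio_median",
    "decline_rate",
    "group_log_anova",
    "model_vs_measured",
    "level_median",
    "read_biomonitoring_csv",
    "write_biomonitoring_csv",
    "BIOMONITORING_PERIOD",
    "COMPARISON_WINDOW",
]

BIOMONITORING_PERIOD = (1960, 2008)
#: default window for medians/contrasts, matching the assessment period
COMPARISON_WINDOW = (1995, 2008)

POPULATIONS = ("TGP", "THEP", "NGP", "NHEP")


@dataclass(frozen=True)
class BiomonitoringRecord:
    """One study-level biomonitoring observation."""

    year: int
    population: str
    sum_ddt: float  # ng/g lipid
    ratio_dde_ddt: float | None = None
    n_individuals: int = 1
    matrix: str = "serum"

    def __post_init__(self) -> None:
        lo, hi = BIOMONITORING_PERIOD
        if not (lo <= self.year <= hi):
            raise ValueError(f"year must be within {lo}-{hi}: {self}")
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.sum_ddt < 0:
            raise ValueError("sum_ddt must be >= 0")
        if self.ratio_dde_ddt is not None and self.ratio_dde_ddt < 0:
            raise ValueError("DDE:DDT ratio must be >= 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


def _select(
    records: Sequence[BiomonitoringRecord],
    population: str | None = None,
    period: tuple[int, int] | None = None,
) -> list[BiomonitoringRecord]:
    out = list(records)
    if population is not None:
        out = [r for r in out if r.population == population]
    if period is not None:
        lo, hi = period
        out = [r for r in out if lo <= r.year <= hi]
    return out


def ratio_median(
    records: Sequence[BiomonitoringRecord],
    population: str,
    period: tuple[int, int] = COMPARISON_WINDOW,
) -> float:
    """Median study-level DDE:DDT ratio for one population and period."""
    ratios = [
        r.ratio_dde_ddt
        for r in _select(records, population, period)
        if r.ratio_dde_ddt is not None
    ]
    if not ratios:
        raise ValueError(
            f"no ratio records for {population} within {period[0]}-{period[1]}"
        )
    return float(np.median(ratios))


def level_median(
    records: Sequence[BiomonitoringRecord],
    population: str,
    period: tuple[int, int] = COMPARISON_WINDOW,
) -> float:
    """Median study-level ΣDDT concentration (ng/g lipid)."""
    levels = [r.sum_ddt for r in _select(records, population, period)]
    if not levels:
        raise ValueError(
            f"no records for {population} within {period[0]}-{period[1]}"
        )
    return float(np.median(levels))


@dataclass(frozen=True)
class DeclineRate:
    """First-order decline rate (1/year) with its 95% confidence interval."""

    rate: float
    ci_low: float
    ci_high: float
    stderr: float
    n: int


def decline_rate(
    records: Sequence[BiomonitoringRecord],
    population: str,
    period: tuple[int, int] | None = None,
) -> DeclineRate:
    """First-order decline rate of ΣDDT from an OLS fit of ln(C) on year.

    The returned rate is the negative of the slope, so a declining series
    yields a positive rate.  Requires >= 3 records over >= 2 distinct
    years with positive concentrations.
    """
    sel = [r for r in _select(records, population, period) if r.sum_ddt > 0]
    if len(sel) < 3:
        raise ValueError("need at least 3 positive records to fit a trend")
    years = np.array([r.year for r in sel], dtype=float)
    if len(np.unique(years)) < 2:
        raise ValueError("records must span at least 2 distinct years")
    y = np.log([r.sum_ddt for r in sel])
    x = sm.add_constant(years)
    fit = sm.OLS(y, x).fit()
    slope = fit.params[1]
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return DeclineRate(
        rate=float(-slope),
        ci_low=float(-hi),
        ci_high=float(-lo),
        stderr=float(fit.bse[1]),
        n=len(sel),
    )


def group_log_anova(
    records: Sequence[BiomonitoringRecord],
    group_a: str,
    group_b: str,
    period: tuple[int, int] = COMPARISON_WINDOW,
    variable: str = "ratio_dde_ddt",
    log_transform: bool = True,
) -> tuple[float, float]:
    """One-way ANOVA contrasting two populations; returns (F, p).

    ``variable`` selects the quantity (``"sum_ddt"`` or ``"ratio_dde_ddt"``);
    values are natural-log transformed by default since both quantities are
    analyzed on log scales.
    """

    def values(pop: str) -> np.ndarray:
        vals = [
            getattr(r, variable)
            for r in _select(records, pop, period)
            if getattr(r, variable) is not None and getattr(r, variable) > 0
        ]
        if len(vals) < 2:
            raise ValueError(f"need >= 2 positive {variable} records for {pop}")
        arr = np.asarray(vals, dtype=float)
        return np.log(arr) if log_transform else arr

    f, p = stats.f_oneway(values(group_a), values(group_b))
    return float(f), float(p)


def model_vs_measured(
    modeled_median: float, measured_median: float
) -> tuple[float, bool]:
    """Symmetric agreement factor max/min >= 1; consistent when < 2."""
    if modeled_median <= 0 or measured_median <= 0:
        raise ValueError("both medians must be > 0")
    factor = max(modeled_median, measured_median) / min(modeled_median, measured_median)
    return float(factor), factor < 2.0


# ---------------------------------------------------------------------------
# CSV interface

BIO_CSV_COLUMNS = ["year", "population", "sum_ddt", "ratio", "n", "matrix"]


def read_biomonitoring_csv(path: str | Path) -> list[BiomonitoringRecord]:
    df = pd.read_csv(path)
    missing = set(BIO_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"biomonitoring CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        ratio = None if pd.isna(row.ratio) else float(row.ratio)
        out.append(
            BiomonitoringRecord(
                year=int(row.year),
                population=row.population,
                sum_ddt=float(row.sum_ddt),
                ratio_dde_ddt=ratio,
                n_individuals=int(row.n),
                matrix=str(row.matrix),
            )
        )
    return out


def write_biomonitoring_csv(
    records: Iterable[BiomonitoringRecord], path: str | Path
) -> None:
    rows = [
        {
            "year": r.year,
            "population": r.population,
            "sum_ddt": r.sum_ddt,
            "ratio": r.ratio_dde_ddt,
            "n": r.n_individuals,
            "matrix": r.matrix,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=BIO_CSV_COLUMNS).to_csv(path, index=False)
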