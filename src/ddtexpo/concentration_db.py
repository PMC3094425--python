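"""Data model and ingestion for exposure-media ΣDDT concentration summaries.

Each record is one study-level central value (mean or median) of ΣDDT in a
single exposure medium for one region/population scope.  The Monte Carlo
engine does not consume the records directly: it consumes sampling
distributions fitted to them here — lognormal for media with several
independent study values, uniform (bounds) where only a range is defensible
(indoor soil/dust in IRS-treated dwellings).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationSummary",
    "LogNormalDist",
    "UniformDist",
    "Distribution",
    "fit_lognormal",
    "sample",
    "derive_seed",
    "read_concentrations_csv",
    "write_concentrations_csv",
    "export_distributions_json",
    "MEDIA_UNITS",
    "FOOD_UNITS",
]

REGIONS = ("Tropics", "North")
SCOPES = ("general", "IRS_indoor", "all")
STATISTICS = ("mean", "median")

#: units for the non-food media; anything else is a food group in ng/g lipid
MEDIA_UNITS = {
    "air_gas": "ng/m3",
    "air_particle": "ng/m3",
    "soil_dust": "ng/mg",
}
FOOD_UNITS = "ng/g lipid"

EXPOSURE_PERIOD = (1995, 2008)


def units_for_medium(medium: str) -> str:
    return MEDIA_UNITS.get(medium, FOOD_UNITS)


@dataclass(frozen=True)
class ConcentrationSummary:
    """One study-level central value of ΣDDT in an exposure medium.

    ``value`` carries medium-specific units: ng/g lipid for food groups,
    ng/m³ for air phases, ng/mg for pooled indoor soil/dust.
    """

    medium: str
    region: str
    population_scope: str
    statistic: str
    value: float
    n_measurements: int = 1
    year_start: int = EXPOSURE_PERIOD[0]
    year_end: int = EXPOSURE_PERIOD[1]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.population_scope not in SCOPES:
            raise ValueError(f"unknown population scope {self.population_scope!r}")
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be mean or median, got {self.statistic!r}")
        if not (self.value >= 0):
            raise ValueError(f"negative concentration in {self}")
        if self.n_measurements < 1:
            raise ValueError("n_measurements must be >= 1")
        lo, hi = EXPOSURE_PERIOD
        if not (lo <= self.year_start <= self.year_end <= hi):
            raise ValueError(
                f"exposure-media period must lie within {lo}-{hi}: {self}"
            )

    @property
    def units(self) -> str:
        return units_for_medium(self.medium)


@dataclass(frozen=True)
class LogNormalDist:
    """Lognormal on the natural-log scale; ``sigma=0`` is a point mass."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def median(self) -> float:
        return math.exp(self.mu)

    def scaled(self, factor: float) -> "LogNormalDist":
        """Multiply the distribution by a positive constant (shifts mu)."""
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        return LogNormalDist(self.mu + math.log(factor), self.sigma)


@dataclass(frozen=True)
class UniformDist:
    """Uniform between two non-negative bounds; equal bounds = point mass."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower < 0 or self.upper < self.lower:
            raise ValueError(f"require 0 <= lower <= upper, got {self}")

    @property
    def median(self) -> float:
        return 0.5 * (self.lower + self.upper)


Distribution = Union[LogNormalDist, UniformDist]


def fit_lognormal(summaries: Sequence[ConcentrationSummary]) -> LogNormalDist:
    """Fit a lognormal to study-level central values of one medium.

    Each published mean/median counts as a single observation on the log
    scale, unweighted by the number of underlying measurements.  ``mu`` is
    the mean of the log values (the log-scale MLE) and ``sigma`` the sample
    standard deviation (n−1 denominator); a single observation yields a
    point mass (``sigma = 0``).
    """
    if len(summaries) == 0:
        raise ValueError("need at least one concentration summary")
    media = {s.medium for s in summaries}
    if len(media) > 1:
        raise ValueError(f"mixed media cannot be pooled: {sorted(media)}")
    for s in summaries:
        if s.value <= 0:
            raise ValueError(f"non-positive concentration cannot be log-fitted: {s}")
    logs = np.log([s.value for s in summaries])
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
    return LogNormalDist(mu=mu, sigma=sigma)


def derive_seed(seed: int, label: str) -> int:
    """Deterministic child seed (< 2^31) for a named random substream."""
    mix = (int(seed) * 2654435761) ^ zlib.crc32(label.encode("utf8"))
    return mix % (2**31)


def sample(dist: Distribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` values; identical (dist, n, seed) gives identical output."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(dist, LogNormalDist):
        return np.exp(rng.normal(dist.mu, dist.sigma, size=n))
    if isinstance(dist, UniformDist):
        return rng.uniform(dist.lower, dist.upper, size=n)
    raise TypeError(f"unsupported distribution type {type(dist).__name__}")


# ---------------------------------------------------------------------------
# CSV / JSON interfaces

CSV_COLUMNS = [
    "medium",
    "region",
    "population_scope",
    "statistic",
    "value",
    "units",
    "n",
    "year_start",
    "year_end",
]


def read_concentrations_csv(path: str | Path) -> list[ConcentrationSummary]:
    """Read the concentration-summary schema, validating units per medium."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"concentration CSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        expected = units_for_medium(row.medium)
        if str(row.units).strip() != expected:
            raise ValueError(
                f"units {row.units!r} do not match medium {row.medium!r}"
                f" (expected {expected!r})"
            )
        out.append(
            ConcentrationSummary(
                medium=row.medium,
                region=row.region,
                population_scope=row.population_scope,
                statistic=row.statistic,
                value=float(row.value),
                n_measurements=int(row.n),
                year_start=int(row.year_start),
                year_end=int(row.year_end),
            )
        )
    return out


def write_concentrations_csv(
    summaries: Iterable[ConcentrationSummary], path: str | Path
) -> None:
    rows = [
        {
            "medium": s.medium,
            "region": s.region,
            "population_scope": s.population_scope,
            "statistic": s.statistic,
            "value": s.value,
            "units": s.units,
            "n": s.n_measurements,
            "year_start": s.year_start,
            "year_end": s.year_end,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def export_distributions_json(
    dists: dict[str, Distribution], path: str | Path
) -> None:
    """Write fitted distribution parameters keyed by medium label."""
    payload = {
        key: {"type": type(d).__name__, **asdict(d)} for key, d in dists.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
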