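"""Monte Carlo convolution of route-specific uptake into total uptake.

The total daily uptake of a population is the sum of its route-specific
uptakes.  Because the routes are driven by independent concentration
distributions, the total-uptake distribution is the convolution of the
route distributions; it is approximated by Monte Carlo sampling: per
iteration one value is drawn from each medium's concentration distribution,
the uptake equations are evaluated with the population's point-estimate
exposure factors, and the routes are summed.  Exposure factors are point
estimates on purpose — concentration variability is the only source of
variability in the output.

Random-number design: each medium gets its own seeded substream derived
deterministically from the run seed and the medium label, so omitting one
route never perturbs the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concentration_db import Distribution, derive_seed, sample
from .uptake_routes import (
    DermalSetting,
    FoodGroupIntake,
    InhalationSetting,
    E_DIET_DEFAULT,
    dermal_uptake_bounds,
    dietary_uptake,
    inhalation_uptake,
)

__all__ = [
    "PopulationProfile",
    "UptakeDistribution",
    "total_uptake_mc",
    "percentiles",
    "route_shares",
    "route_omission_factor",
    "adi_exceedance",
    "POPULATIONS",
    "ROUTES",
    "N_ITER_DEFAULT",
    "ADI_DEFAULT",
    "BODY_WEIGHT_DEFAULT",
]

POPULATIONS = ("TGP", "THEP", "NGP", "NHEP")
ROUTES = ("diet", "inhalation", "dermal")

#: Monte Carlo iterations per assessment run
N_ITER_DEFAULT = 2000
#: acceptable daily intake, µg per kg body weight per day
ADI_DEFAULT = 20.0
#: reference adult body weight, kg
BODY_WEIGHT_DEFAULT = 65.0

# medium keys the engine looks up in a profile's concentration_dists
OUTDOOR_GAS = "air_gas"
INDOOR_GAS = "air_gas_indoor"
INDOOR_PARTICLE = "air_particle_indoor"
DERMAL_MEDIUM = "dermal_soil_dust"


@dataclass(frozen=True)
class PopulationProfile:
    """Exposure factors, route switches and concentration distributions
    for one of the four populations (TGP, THEP, NGP, NHEP)."""

    population: str
    routes: tuple[str, ...]
    intakes: tuple[FoodGroupIntake, ...] = ()
    inhalation: InhalationSetting | None = None
    dermal: DermalSetting | None = None
    concentration_dists: Mapping[str, Distribution] = field(default_factory=dict)
    e_diet: float = E_DIET_DEFAULT

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        unknown = set(self.routes) - set(ROUTES)
        if unknown:
            raise ValueError(f"unknown routes {sorted(unknown)}")
        if ("dermal" in self.routes) != (self.dermal is not None):
            raise ValueError(
                "dermal setting must be present exactly when the dermal route is on"
            )
        if "inhalation" in self.routes and self.inhalation is None:
            raise ValueError("inhalation route switched on without a setting")
        self._check_media()

    def _check_media(self) -> None:
        dists = self.concentration_dists
        if "diet" in self.routes:
            for intake in self.intakes:
                if intake.food_group not in dists:
                    raise ValueError(
                        f"{self.population}: missing concentration distribution "
                        f"for food group {intake.food_group!r}"
                    )
        if "inhalation" in self.routes:
            if OUTDOOR_GAS not in dists:
                raise ValueError(
                    f"{self.population}: missing outdoor gas-phase air distribution"
                )
            if self.inhalation is not None and not self.inhalation.indoor_equals_outdoor:
                for key in (INDOOR_GAS, INDOOR_PARTICLE):
                    if key not in dists:
                        raise ValueError(
                            f"{self.population}: missing indoor air distribution {key!r}"
                        )


@dataclass(frozen=True)
class UptakeDistribution:
    """Route-resolved Monte Carlo uptake samples, ng/person/day.

    ``samples`` has one column per active route plus a ``total`` column that
    equals the row-wise sum of the route columns exactly.  ``diet_groups``
    keeps the per-food-group breakdown of the diet column for reporting.
    """

    samples: pd.DataFrame
    n_iter: int
    seed: int
    population: str
    diet_groups: pd.DataFrame | None = None

    @property
    def routes(self) -> list[str]:
        return [c for c in self.samples.columns if c != "total"]

    @property
    def total(self) -> np.ndarray:
        return self.samples["total"].to_numpy()


def total_uptake_mc(
    profile: PopulationProfile,
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
    exclude_routes: Sequence[str] = (),
) -> UptakeDistribution:
    """Monte Carlo total-uptake distribution for one population.

    ``exclude_routes`` drops routes without touching the other routes'
    random draws (used by :func:`route_omission_factor`).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    for r in exclude_routes:
        if r not in profile.routes:
            raise ValueError(f"route {r!r} is not active in {profile.population}")
    active = [r for r in profile.routes if r not in exclude_routes]

    def draw(key: str) -> np.ndarray:
        dist = profile.concentration_dists[key]
        return sample(dist, n_iter, derive_seed(seed, key))

    cols: dict[str, np.ndarray] = {}
    diet_groups = None
    if "diet" in active:
        conc = {i.food_group: draw(i.food_group) for i in profile.intakes}
        per_group, total_diet = dietary_uptake(profile.intakes, conc, profile.e_diet)
        cols["diet"] = np.asarray(total_diet, dtype=float)
        diet_groups = pd.DataFrame(per_group)
    if "inhalation" in active:
        setting = profile.inhalation
        assert setting is not None
        out = draw(OUTDOOR_GAS)
        if setting.indoor_equals_outdoor:
            cols["inhalation"] = inhalation_uptake(setting, out)
        else:
            cols["inhalation"] = inhalation_uptake(
                setting, out, draw(INDOOR_GAS), draw(INDOOR_PARTICLE)
            )
    if "dermal" in active:
        assert profile.dermal is not None
        dist = dermal_uptake_bounds(profile.dermal)
        cols["dermal"] = sample(dist, n_iter, derive_seed(seed, DERMAL_MEDIUM))

    samples = pd.DataFrame(cols)
    samples["total"] = samples.sum(axis=1)
    return UptakeDistribution(
        samples=samples,
        n_iter=n_iter,
        seed=seed,
        population=profile.population,
        diet_groups=diet_groups,
    )


def percentiles(
    dist: UptakeDistribution, probs: Sequence[float] = (5, 25, 50, 75, 95)
) -> pd.DataFrame:
    """Percentiles per route and total, linear interpolation between order
    statistics.  ``probs`` are in percent, open interval (0, 100)."""
    probs = list(probs)
    if len(dist.samples) == 0:
        raise ValueError("empty sample set")
    if any(not (0 < p < 100) for p in probs):
        raise ValueError("percentile probabilities must lie in (0, 100)")
    values = np.percentile(
        dist.samples.to_numpy(), probs, axis=0, method="linear"
    )
    return pd.DataFrame(values, index=probs, columns=dist.samples.columns)


def route_shares(dist: UptakeDistribution) -> dict[str, float]:
    """Median route uptake as a percentage of median total uptake.

    Shares are ratios of medians (not medians of ratios) and therefore
    need not sum to exactly 100%.
    """
    med_total = float(np.median(dist.total))
    if med_total <= 0:
        raise ValueError("median total uptake must be > 0 for route shares")
    return {
        r: 100.0 * float(np.median(dist.samples[r])) / med_total
        for r in dist.routes
    }


def route_omission_factor(
    profile: PopulationProfile,
    route: str,
    n_iter: int = N_ITER_DEFAULT,
    seed: int = 0,
) -> float:
    """Median total uptake with a route included over that with it omitted.

    Both runs reuse the same per-medium random substreams, so the factor
    isolates the route's contribution exactly.
    """
    if route not in profile.routes:
        raise ValueError(f"route {route!r} is not active in {profile.population}")
    full = total_uptake_mc(profile, n_iter=n_iter, seed=seed)
    reduced = total_uptake_mc(profile, n_iter=n_iter, seed=seed, exclude_routes=(route,))
    med_reduced = float(np.median(reduced.total))
    if med_reduced <= 0:
        raise ValueError("median total uptake without the route is not positive")
    return float(np.median(full.total)) / med_reduced


def adi_exceedance(
    dist: UptakeDistribution,
    adi: float = ADI_DEFAULT,
    body_weight: float = BODY_WEIGHT_DEFAULT,
) -> tuple[float, float]:
    """ADI threshold in ng/day and the fraction of samples exceeding it.

    threshold = ADI (µg/kg/day) · body weight (kg) · 1000 (ng/µg); the
    default 20 µg/kg/day for a 65-kg adult gives 1.3e6 ng/day.
    """
    if adi <= 0 or body_weight <= 0:
        raise ValueError("adi and body weight must be > 0")
    threshold = adi * body_weight * 1000.0
    fraction = float(np.mean(dist.total > threshold))
    return threshold, fraction


def without_route(profile: PopulationProfile, route: str) -> PopulationProfile:
    """Profile copy with one route switched off (dermal setting dropped)."""
    routes = tuple(r for r in profile.routes if r != route)
    dermal = profile.dermal if "dermal" in routes else None
    return replace(profile, routes=routes, dermal=dermal)
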