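"""Route-specific ΣDDT uptake: diet, inhalation, and dermal contact.

Uptake is intake multiplied by a route-specific absorption efficiency.  All
outputs are in ng per person per day; concentrations keep their
medium-specific units (ng/g lipid for food, ng/m³ for air, ng/mg for
soil/dust) and the conversion constants are carried explicitly by the
equations.  Every operator is linear in its concentration arguments and
accepts scalars or numpy arrays (one value per Monte Carlo iteration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .concentration_db import UniformDist

__all__ = [
    "FoodGroupIntake",
    "InhalationSetting",
    "DermalSetting",
    "dietary_uptake",
    "inhalation_uptake",
    "dermal_uptake_bounds",
    "indoor_air_mass_balance",
    "E_DIET_DEFAULT",
    "E_GAS_DEFAULT",
    "E_PARTICLE_DEFAULT",
    "E_INH_GENERIC",
]

#: dietary uptake efficiency (gastrointestinal absorption of ΣDDT)
E_DIET_DEFAULT = 0.9
#: inhalation uptake efficiency, gas phase
E_GAS_DEFAULT = 1.0
#: inhalation uptake efficiency, particle phase
E_PARTICLE_DEFAULT = 0.44
#: generic alternative efficiency applied to both phases when selected
E_INH_GENERIC = 0.75


@dataclass(frozen=True)
class FoodGroupIntake:
    """Point-estimate consumption of one food group.

    ``m`` in g food/person/day; ``f_lipid`` in g lipid/g food.
    """

    food_group: str
    m: float
    f_lipid: float

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"consumption must be >= 0 ({self.food_group})")
        if not (0.0 <= self.f_lipid <= 1.0):
            raise ValueError(f"lipid fraction must be in [0,1] ({self.food_group})")


@dataclass(frozen=True)
class InhalationSetting:
    """Inhalation exposure factors for one population.

    ``indoor_equals_outdoor`` encodes the assumption that indoor air carries
    the outdoor concentration (all populations except those in IRS-treated
    dwellings), in which case the indoor/outdoor time split is irrelevant
    and uptake collapses to ``V_inh · C_outdoor_gas · E_gas``.
    """

    v_inh: float  # m³/person/day
    indoor_fraction: float = 1.0 / 3.0  # 8 h/day indoors
    e_gas: float = E_GAS_DEFAULT
    e_particle: float = E_PARTICLE_DEFAULT
    indoor_equals_outdoor: bool = True

    def __post_init__(self) -> None:
        if self.v_inh <= 0:
            raise ValueError("inhalation rate must be > 0")
        if not (0.0 <= self.indoor_fraction <= 1.0):
            raise ValueError("indoor fraction must be in [0,1]")
        for e in (self.e_gas, self.e_particle):
            if not (0.0 <= e <= 1.0):
                raise ValueError("uptake efficiencies must be in [0,1]")

    def with_generic_efficiency(self) -> "InhalationSetting":
        """Variant with the generic 75% efficiency for both phases."""
        return InhalationSetting(
            v_inh=self.v_inh,
            indoor_fraction=self.indoor_fraction,
            e_gas=E_INH_GENERIC,
            e_particle=E_INH_GENERIC,
            indoor_equals_outdoor=self.indoor_equals_outdoor,
        )


@dataclass(frozen=True)
class DermalSetting:
    """Dermal exposure factors for indoor soil/dust contact.

    SDA in mg/cm², AE bounds in cm²/person, C_sd bounds in ng/mg,
    UR_derm in 1/day.  Soil and dust are one pooled medium.
    """

    sda: float = 1.0
    ae_min: float = 1120.0  # feet only
    ae_max: float = 9550.0  # full upper and lower extremities
    c_sd_min: float = 0.0
    c_sd_max: float = 0.0
    ur_derm: float = 0.01

    def __post_init__(self) -> None:
        for name in ("sda", "ae_min", "ae_max", "c_sd_min", "c_sd_max", "ur_derm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ae_min > self.ae_max:
            raise ValueError("ae_min must be <= ae_max")
        if self.c_sd_min > self.c_sd_max:
            raise ValueError("c_sd_min must be <= c_sd_max")


def dietary_uptake(
    intakes: Sequence[FoodGroupIntake],
    concentrations: Mapping[str, float | np.ndarray],
    e_diet: float = E_DIET_DEFAULT,
) -> tuple[dict[str, np.ndarray | float], np.ndarray | float]:
    """Daily dietary uptake per food group and in total.

    U_diet,i = m_i · f_lipid,i · C_i · E_diet, with C_i lipid-normalized
    (ng/g lipid).  Returns ``(per_group, total)``.
    """
    if not (0.0 <= e_diet <= 1.0):
        raise ValueError("e_diet must be in [0,1]")
    per_group: dict[str, np.ndarray | float] = {}
    for intake in intakes:
        if intake.food_group not in concentrations:
            raise KeyError(
                f"no concentration supplied for consumed food group "
                f"{intake.food_group!r}"
            )
        c = np.asarray(concentrations[intake.food_group], dtype=float)
        if np.any(c < 0):
            raise ValueError(f"negative concentration for {intake.food_group!r}")
        per_group[intake.food_group] = intake.m * intake.f_lipid * c * e_diet
    total = sum(per_group.values()) if per_group else 0.0
    return per_group, total


def inhalation_uptake(
    setting: InhalationSetting,
    c_outdoor_gas: float | np.ndarray,
    c_indoor_gas: float | np.ndarray = 0.0,
    c_indoor_particle: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Daily inhalation uptake from outdoor and indoor air (ng/person/day).

    Outdoor exposure uses the gas phase only.  Indoor exposure (IRS-treated
    dwellings) adds gas- and particle-phase contributions with their
    respective efficiencies during the indoor time fraction.
    """
    out = np.asarray(c_outdoor_gas, dtype=float)
    gas = np.asarray(c_indoor_gas, dtype=float)
    part = np.asarray(c_indoor_particle, dtype=float)
    if np.any(out < 0) or np.any(gas < 0) or np.any(part < 0):
        raise ValueError("air concentrations must be >= 0")
    if setting.indoor_equals_outdoor:
        u = setting.v_inh * out * setting.e_gas
    else:
        f_in = setting.indoor_fraction
        u = setting.v_inh * (
            (1.0 - f_in) * out * setting.e_gas
            + f_in * (gas * setting.e_gas + part * setting.e_particle)
        )
    return u if u.ndim else float(u)


def dermal_uptake_bounds(setting: DermalSetting) -> UniformDist:
    """Bounding uniform distribution of dermal uptake (ng/person/day).

    Lower/upper bounds are products of the minimal/maximal skin area and
    soil-dust concentration with the adherence and the dermal uptake rate:
    U = SDA · AE · C_sd · UR_derm.
    """
    lower = setting.sda * setting.ae_min * setting.c_sd_min * setting.ur_derm
    upper = setting.sda * setting.ae_max * setting.c_sd_max * setting.ur_derm
    return UniformDist(lower=lower, upper=upper)


def indoor_air_mass_balance(
    emission_flux: float,
    treated_area: float,
    room_volume: float,
    air_exchange_rate: float,
) -> float:
    """Steady-state indoor air concentration from wall evaporation (ng/m³).

    Well-mixed box: emission from IRS-treated wall area balanced by air
    exchange, C = flux · area / (exchange · volume).  Screening model for
    checking measured indoor IRS concentrations (order 1–10 µg/m³).
    """
    if emission_flux < 0:
        raise ValueError("emission flux must be >= 0")
    if treated_area <= 0:
        raise ValueError("treated area must be > 0")
    if room_volume <= 0 or air_exchange_rate <= 0:
        raise ValueError("no steady state without positive volume and air exchange")
    return emission_flux * treated_area / (air_exchange_rate * room_volume)
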