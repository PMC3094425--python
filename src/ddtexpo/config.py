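"""Run configuration and default exposure factors.

Several exposure factors stand in for values that are not fixed by the
assessment's published description (the inhalation rate, the dermal uptake
rate constant, the body lipid mass, food consumption rates).  They are
plain configuration with documented defaults — never hard-coded inside the
uptake equations — and every default is echoed into the report's
provenance block marked as an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .uptake_routes import DermalSetting, FoodGroupIntake, InhalationSetting
from .exposure_engine import (
    ADI_DEFAULT,
    BODY_WEIGHT_DEFAULT,
    N_ITER_DEFAULT,
    POPULATIONS,
)
from .pk_model import BODY_LIPID_MASS_DEFAULT, T_HALF_DDE, T_HALF_DDT

__all__ = [
    "RunConfig",
    "default_intakes",
    "default_inhalation",
    "default_dermal",
    "AQUATIC_FOOD_GROUPS",
    "V_INH_DEFAULT",
    "DEFAULT_DDE_DDT_INTAKE_RATIOS",
]

#: generic average adult inhalation rate, m³/person/day (assumption)
V_INH_DEFAULT = 15.0
#: fraction of the day spent indoors for the IRS-exposed population (8 h/day)
INDOOR_FRACTION_THEP = 8.0 / 24.0

#: food groups counted as the aquatic food web in reports
AQUATIC_FOOD_GROUPS = frozenset({"fish_freshwater", "fish_marine", "marine_mammals"})

#: fallback DDE:DDT intake composition when biomonitoring ratios are absent
DEFAULT_DDE_DDT_INTAKE_RATIOS = {"TGP": 8.5, "THEP": 2.7, "NGP": 9.0, "NHEP": 8.0}

_TROPICS_INTAKES = (
    FoodGroupIntake("dairy", 150.0, 0.04),
    FoodGroupIntake("meat", 100.0, 0.15),
    FoodGroupIntake("grains", 400.0, 0.02),
    FoodGroupIntake("fish_freshwater", 30.0, 0.05),
)
_NGP_INTAKES = (
    FoodGroupIntake("dairy", 250.0, 0.04),
    FoodGroupIntake("meat", 150.0, 0.20),
    FoodGroupIntake("grains", 250.0, 0.02),
    FoodGroupIntake("fish_marine", 40.0, 0.05),
)
_NHEP_INTAKES = _NGP_INTAKES + (FoodGroupIntake("marine_mammals", 50.0, 0.30),)


def default_intakes(population: str) -> tuple[FoodGroupIntake, ...]:
    """Point-estimate food consumption basket for one population."""
    if population in ("TGP", "THEP"):
        return _TROPICS_INTAKES
    if population == "NGP":
        return _NGP_INTAKES
    if population == "NHEP":
        return _NHEP_INTAKES
    raise ValueError(f"unknown population {population!r}")


def default_inhalation(population: str, generic_efficiency: bool = False) -> InhalationSetting:
    """Inhalation setting; only the IRS population resolves indoor air."""
    setting = InhalationSetting(
        v_inh=V_INH_DEFAULT,
        indoor_fraction=INDOOR_FRACTION_THEP,
        indoor_equals_outdoor=(population != "THEP"),
    )
    return setting.with_generic_efficiency() if generic_efficiency else setting


def default_dermal(c_sd_min: float, c_sd_max: float) -> DermalSetting:
    """Dermal setting with bounding skin areas and pooled soil/dust bounds."""
    return DermalSetting(c_sd_min=c_sd_min, c_sd_max=c_sd_max)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    n_iter: int = N_ITER_DEFAULT
    seed: int = 0
    populations: tuple[str, ...] = POPULATIONS
    percentile_probs: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)
    adi: float = ADI_DEFAULT
    body_weight: float = BODY_WEIGHT_DEFAULT
    body_lipid_mass: float = BODY_LIPID_MASS_DEFAULT
    t_half_ddt: float = T_HALF_DDT
    t_half_dde: float = T_HALF_DDE
    pk_weighting: str = "rate"
    generic_inhalation_efficiency: bool = False
    dde_ddt_intake_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DDE_DDT_INTAKE_RATIOS)
    )
    ratios_from_biomonitoring: bool = True
    concentrations_csv: str | None = None
    biomonitoring_csv: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        unknown = set(self.populations) - set(POPULATIONS)
        if unknown:
            raise ValueError(f"unknown populations {sorted(unknown)}")
        if any(not (0 < p < 100) for p in self.percentile_probs):
            raise ValueError("percentile probabilities must lie in (0, 100)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "populations" in raw:
            raw["populations"] = tuple(raw["populations"])
        if "percentile_probs" in raw:
            raw["percentile_probs"] = tuple(raw["percentile_probs"])
        return cls(**raw)

    def assumptions(self) -> dict[str, object]:
        """Defaults standing in for unpublished values, for provenance."""
        return {
            "inhalation_rate_m3_per_day": V_INH_DEFAULT,
            "dermal_uptake_rate_per_day": DermalSetting().ur_derm,
            "body_lipid_mass_kg": self.body_lipid_mass,
            "dde_ddt_intake_ratios": dict(self.dde_ddt_intake_ratios),
            "food_consumption_point_estimates": True,
        }
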