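import numpy as np
import pytest

from ddtexpo.concentration_db import LogNormalDist
from ddtexpo.exposure_engine import PopulationProfile, OUTDOOR_GAS
from ddtexpo.uptake_routes import FoodGroupIntake, InhalationSetting


def make_two_route_profile(diet_uptake: float, inhalation_uptake: float) -> PopulationProfile:
    """Profile with two degenerate routes yielding exactly the given uptakes.

    Diet: one food group with m=diet_uptake g/day, f_lipid=1, C=1 ng/g,
    E_diet=1.  Inhalation: V_inh=10 m³/day at a point-mass outdoor gas
    concentration of inhalation_uptake/10 ng/m³.
    """
    return PopulationProfile(
        population="TGP",
        routes=("diet", "inhalation"),
        intakes=(FoodGroupIntake("staple", diet_uptake, 1.0),),
        inhalation=InhalationSetting(v_inh=10.0, indoor_equals_outdoor=True),
        concentration_dists={
            "staple": LogNormalDist(mu=0.0, sigma=0.0),
            OUTDOOR_GAS: LogNormalDist(mu=np.log(inhalation_uptake / 10.0), sigma=0.0),
        },
        e_diet=1.0,
    )


@pytest.fixture
def two_route_profile() -> PopulationProfile:
    """Degenerate routes of 250 (inhalation) and 100 (diet) ng/person/day."""
    return make_two_route_profile(100.0, 250.0)
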