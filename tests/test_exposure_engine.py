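"""Monte Carlo convolution, percentile reporting and sensitivity ops."""

import math

import numpy as np
import pandas as pd
import pytest

from ddtexpo.concentration_db import LogNormalDist
from ddtexpo.exposure_engine import (
    OUTDOOR_GAS,
    PopulationProfile,
    UptakeDistribution,
    adi_exceedance,
    percentiles,
    route_omission_factor,
    route_shares,
    total_uptake_mc,
)
from ddtexpo.uptake_routes import FoodGroupIntake, InhalationSetting

from conftest import make_two_route_profile


def single_route_profile(mu=2.0, sigma=0.5, m=100.0, f_lipid=0.04, e_diet=0.9):
    return PopulationProfile(
        population="TGP",
        routes=("diet",),
        intakes=(FoodGroupIntake("dairy", m, f_lipid),),
        concentration_dists={"dairy": LogNormalDist(mu, sigma)},
        e_diet=e_diet,
    )


def make_dist(total_values, route="diet"):
    df = pd.DataFrame({route: np.asarray(total_values, dtype=float)})
    df["total"] = df.sum(axis=1)
    return UptakeDistribution(samples=df, n_iter=len(df), seed=0, population="TGP")


class TestTotalUptakeMC:
    def test_degenerate_distributions_give_constant_total(self, two_route_profile):
        dist = total_uptake_mc(two_route_profile, n_iter=50, seed=3)
        assert np.all(dist.total == pytest.approx(350.0))

    def test_default_iteration_count(self):
        dist = total_uptake_mc(single_route_profile(), seed=0)
        assert dist.n_iter == 2000
        assert len(dist.samples) == 2000

    def test_mc_median_matches_closed_form(self):
        # lognormal times constants is lognormal: median = e^mu * m * f * E
        dist = total_uptake_mc(single_route_profile(), n_iter=100_000, seed=5)
        expected = math.exp(2.0) * 100.0 * 0.04 * 0.9
        assert np.median(dist.total) == pytest.approx(expected, rel=0.02)

    def test_total_is_rowwise_sum_of_routes_exactly(self, two_route_profile):
        dist = total_uptake_mc(two_route_profile, n_iter=200, seed=9)
        recomputed = dist.samples[dist.routes].sum(axis=1).to_numpy()
        assert np.array_equal(dist.total, recomputed)

    def test_seed_determinism(self):
        p = single_route_profile()
        a = total_uptake_mc(p, n_iter=500, seed=42)
        b = total_uptake_mc(p, n_iter=500, seed=42)
        assert a.samples.equals(b.samples)
        assert not a.samples.equals(total_uptake_mc(p, n_iter=500, seed=43).samples)

    def test_scaling_concentration_location_scales_percentiles(self):
        lam = 7.0
        base = single_route_profile(mu=1.0, sigma=0.6)
        scaled = single_route_profile(mu=1.0 + math.log(lam), sigma=0.6)
        pa = percentiles(total_uptake_mc(base, n_iter=2000, seed=8), [5, 50, 95])
        pb = percentiles(total_uptake_mc(scaled, n_iter=2000, seed=8), [5, 50, 95])
        assert np.allclose(pb["total"], lam * pa["total"], rtol=1e-9)

    def test_missing_distribution_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PopulationProfile(
                population="TGP",
                routes=("inhalation",),
                inhalation=InhalationSetting(v_inh=15.0),
                concentration_dists={},
            )

    def test_dermal_requires_setting(self):
        with pytest.raises(ValueError, match="dermal"):
            PopulationProfile(population="THEP", routes=("dermal",), dermal=None)


class TestPercentiles:
    def test_constant_samples(self):
        p = percentiles(make_dist([3.0] * 10), [5, 50, 95])
        assert np.all(p["total"] == 3.0)

    def test_linear_interpolation_rule(self):
        p = percentiles(make_dist(np.arange(1, 101)), [50])
        assert p.loc[50, "total"] == pytest.approx(50.5)

    def test_monotone_in_probability(self):
        rng = np.random.default_rng(0)
        p = percentiles(make_dist(rng.lognormal(1, 1, 500)), [25, 50, 75])
        t = p["total"].to_numpy()
        assert t[0] <= t[1] <= t[2]

    def test_rejects_out_of_range_probs(self):
        with pytest.raises(ValueError):
            percentiles(make_dist([1.0, 2.0]), [0])
        with pytest.raises(ValueError):
            percentiles(make_dist([1.0, 2.0]), [100])


class TestRouteShares:
    def test_single_route_is_hundred_percent(self):
        shares = route_shares(make_dist([10.0, 20.0, 30.0]))
        assert shares == {"diet": pytest.approx(100.0)}

    def test_two_degenerate_routes(self, two_route_profile):
        dist = total_uptake_mc(two_route_profile, n_iter=100, seed=1)
        shares = route_shares(dist)
        assert shares["inhalation"] == pytest.approx(250.0 / 350.0 * 100.0)
        assert shares["diet"] == pytest.approx(100.0 / 350.0 * 100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            route_shares(make_dist([0.0, 0.0]))


class TestRouteOmission:
    def test_omitting_zero_route_gives_factor_one(self):
        profile = make_two_route_profile(100.0, 1e-300)
        # inhalation contributes ~0: factor of totals is 1
        assert route_omission_factor(profile, "inhalation", n_iter=50, seed=2) == (
            pytest.approx(1.0)
        )

    def test_two_degenerate_routes_factor(self, two_route_profile):
        f = route_omission_factor(two_route_profile, "inhalation", n_iter=100, seed=4)
        assert f == pytest.approx(3.5)

    def test_omission_does_not_perturb_other_routes(self, two_route_profile):
        full = total_uptake_mc(two_route_profile, n_iter=100, seed=6)
        reduced = total_uptake_mc(
            two_route_profile, n_iter=100, seed=6, exclude_routes=("inhalation",)
        )
        assert np.array_equal(
            full.samples["diet"].to_numpy(), reduced.samples["diet"].to_numpy()
        )

    def test_inactive_route_rejected(self, two_route_profile):
        with pytest.raises(ValueError, match="dermal"):
            route_omission_factor(two_route_profile, "dermal")


class TestADIExceedance:
    def test_threshold_for_default_adult(self):
        threshold, _ = adi_exceedance(make_dist([1.0]), adi=20.0, body_weight=65.0)
        assert threshold == pytest.approx(1.3e6)

    def test_all_below_threshold(self):
        _, frac = adi_exceedance(make_dist([10.0, 20.0]))
        assert frac == 0.0

    def test_degenerate_distribution_above_threshold(self):
        _, frac = adi_exceedance(make_dist([2e6] * 100))
        assert frac == 1.0
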