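"""Pipeline orchestration and report generation.

``run_pipeline`` wires the stages together: fit sampling distributions to
the concentration summaries, build the four population profiles, run the
Monte Carlo uptake convolution, translate uptake to body burdens with the
steady-state PK model, and evaluate against the biomonitoring records
(levels, trends, DDE:DDT ratios, agreement factors).  The report is a
plain JSON-serializable dict; with an output directory set, the samples
are also written as tidy CSV.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import biomonitoring_eval as bio
from .concentration_db import (
    ConcentrationSummary,
    Distribution,
    UniformDist,
    derive_seed,
    fit_lognormal,
    read_concentrations_csv,
)
from .config import (
    AQUATIC_FOOD_GROUPS,
    RunConfig,
    default_dermal,
    default_inhalation,
    default_intakes,
)
from .exposure_engine import (
    INDOOR_GAS,
    INDOOR_PARTICLE,
    OUTDOOR_GAS,
    PopulationProfile,
    UptakeDistribution,
    adi_exceedance,
    percentiles,
    route_omission_factor,
    route_shares,
    total_uptake_mc,
)
from .pk_model import PKParameters, dose_weighted_halflife, modeled_body_burden
from .synthetic_data import default_scenario, generate_biomonitoring, generate_concentrations

__all__ = [
    "fit_media_distributions",
    "build_profiles",
    "run_pipeline",
]

log = logging.getLogger("ddtexpo")

MediaKey = tuple[str, str, str]  # (medium, region, population_scope)


def fit_media_distributions(
    summaries: Sequence[ConcentrationSummary],
) -> dict[MediaKey, Distribution]:
    """Fit one sampling distribution per (medium, region, scope).

    Lognormal everywhere except pooled indoor soil/dust, whose sparse data
    only support a bounding uniform (min to max of the reported values).
    """
    groups: dict[MediaKey, list[ConcentrationSummary]] = {}
    for s in summaries:
        groups.setdefault((s.medium, s.region, s.population_scope), []).append(s)
    dists: dict[MediaKey, Distribution] = {}
    for key, grp in groups.items():
        if key[0] == "soil_dust":
            values = [s.value for s in grp]
            dists[key] = UniformDist(min(values), max(values))
        else:
            dists[key] = fit_lognormal(grp)
    return dists


def _require(dists: Mapping[MediaKey, Distribution], key: MediaKey) -> Distribution:
    if key not in dists:
        raise ValueError(f"no fitted distribution for medium {key}")
    return dists[key]


def build_profiles(
    dists: Mapping[MediaKey, Distribution],
    config: RunConfig | None = None,
) -> dict[str, PopulationProfile]:
    """Assemble the four population profiles from fitted media distributions.

    Route switches: every population takes diet and inhalation; only the
    IRS-dwelling population (THEP) resolves indoor air and adds the dermal
    route.
    """
    config = config or RunConfig()
    profiles: dict[str, PopulationProfile] = {}
    for pop in config.populations:
        region = "Tropics" if pop in ("TGP", "THEP") else "North"
        food_scope = "general" if region == "Tropics" else "all"
        intakes = default_intakes(pop)
        conc: dict[str, Distribution] = {
            i.food_group: _require(dists, (i.food_group, region, food_scope))
            for i in intakes
        }
        conc[OUTDOOR_GAS] = _require(dists, ("air_gas", region, "general"))
        routes: tuple[str, ...] = ("diet", "inhalation")
        dermal = None
        if pop == "THEP":
            conc[INDOOR_GAS] = _require(dists, ("air_gas", "Tropics", "IRS_indoor"))
            conc[INDOOR_PARTICLE] = _require(
                dists, ("air_particle", "Tropics", "IRS_indoor")
            )
            sd = _require(dists, ("soil_dust", "Tropics", "IRS_indoor"))
            if not isinstance(sd, UniformDist):
                raise ValueError("soil/dust must be a bounding uniform distribution")
            dermal = default_dermal(sd.lower, sd.upper)
            routes = ("diet", "inhalation", "dermal")
        profiles[pop] = PopulationProfile(
            population=pop,
            routes=routes,
            intakes=intakes,
            inhalation=default_inhalation(
                pop, generic_efficiency=config.generic_inhalation_efficiency
            ),
            dermal=dermal,
            concentration_dists=conc,
        )
    return profiles


def _diet_web_medians(dist: UptakeDistribution) -> dict[str, float]:
    """Median agricultural vs aquatic dietary uptake, ng/person/day."""
    if dist.diet_groups is None:
        return {}
    agri = [c for c in dist.diet_groups.columns if c not in AQUATIC_FOOD_GROUPS]
    aqua = [c for c in dist.diet_groups.columns if c in AQUATIC_FOOD_GROUPS]
    out = {}
    if agri:
        out["diet_agricultural"] = float(
            np.median(dist.diet_groups[agri].sum(axis=1))
        )
    if aqua:
        out["diet_aquatic"] = float(np.median(dist.diet_groups[aqua].sum(axis=1)))
    return out


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full assessment and return the report bundle."""
    config = config or RunConfig()
    log.info("pipeline start: seed=%d n_iter=%d", config.seed, config.n_iter)

    # --- inputs ------------------------------------------------------------
    if config.concentrations_csv:
        summaries = read_concentrations_csv(config.concentrations_csv)
    else:
        summaries = generate_concentrations(default_scenario(seed=config.seed))
    if config.biomonitoring_csv:
        records = bio.read_biomonitoring_csv(config.biomonitoring_csv)
    else:
        records = generate_biomonitoring(default_scenario(seed=config.seed))

    dists = fit_media_distributions(summaries)
    profiles = build_profiles(dists, config)

    report: dict = {
        "config": {
            "seed": config.seed,
            "n_iter": config.n_iter,
            "populations": list(config.populations),
            "adi_ug_per_kg_day": config.adi,
            "body_weight_kg": config.body_weight,
            "pk_weighting": config.pk_weighting,
            "assumptions": config.assumptions(),
            "synthetic_inputs": config.concentrations_csv is None,
        },
        "populations": {},
        "biomonitoring": {},
        "sensitivity": {},
    }

    uptakes: dict[str, UptakeDistribution] = {}
    for pop, profile in profiles.items():
        mc_seed = derive_seed(config.seed, f"mc:{pop}")
        dist = total_uptake_mc(profile, n_iter=config.n_iter, seed=mc_seed)
        uptakes[pop] = dist

        # intake composition: prefer measured window ratios, else config
        ratio = config.dde_ddt_intake_ratios.get(pop)
        if config.ratios_from_biomonitoring:
            try:
                ratio = bio.ratio_median(records, pop)
            except ValueError:
                log.warning("no ratio data for %s; using configured ratio", pop)
        params = PKParameters(
            uptake_ratio_dde_ddt=float(ratio),
            t_half_ddt=config.t_half_ddt,
            t_half_dde=config.t_half_dde,
            body_lipid_mass=config.body_lipid_mass,
            weighting=config.pk_weighting,
        )
        burden = modeled_body_burden(dist, params)
        pcts = percentiles(dist, config.percentile_probs)
        threshold, exceed = adi_exceedance(dist, config.adi, config.body_weight)

        modeled_median = float(np.median(burden))
        entry = {
            "uptake_percentiles_ng_per_day": {
                col: {f"P{int(p)}": float(pcts.loc[p, col]) for p in pcts.index}
                for col in pcts.columns
            },
            "route_shares_pct": route_shares(dist),
            "diet_web_medians_ng_per_day": _diet_web_medians(dist),
            "adi": {
                "threshold_ng_per_day": threshold,
                "exceedance_fraction": exceed,
            },
            "pk": {
                "dde_ddt_intake_ratio": float(ratio),
                "dose_weighted_half_life_years": dose_weighted_halflife(params),
            },
            "modeled_median_ng_per_g_lipid": modeled_median,
            "body_burden_percentiles_ng_per_g_lipid": {
                f"P{int(p)}": float(np.percentile(burden, p))
                for p in config.percentile_probs
            },
        }
        try:
            measured = bio.level_median(records, pop)
            factor, consistent = bio.model_vs_measured(modeled_median, measured)
            entry["measured_median_ng_per_g_lipid"] = measured
            entry["agreement_factor"] = factor
            entry["consistent_within_factor_2"] = consistent
        except ValueError:
            log.warning("no biomonitoring levels for %s in the window", pop)
        report["populations"][pop] = entry

    # --- biomonitoring summary ----------------------------------------------
    ratio_medians, declines = {}, {}
    for pop in config.populations:
        try:
            ratio_medians[pop] = bio.ratio_median(records, pop)
        except ValueError:
            pass
        try:
            d = bio.decline_rate(records, pop)
            declines[pop] = {
                "rate_per_year": d.rate,
                "ci95": [d.ci_low, d.ci_high],
                "n": d.n,
            }
        except ValueError:
            pass
    report["biomonitoring"]["ratio_medians"] = ratio_medians
    report["biomonitoring"]["decline_rates"] = declines
    if {"TGP", "THEP"} <= set(config.populations):
        f_stat, p_val = bio.group_log_anova(records, "TGP", "THEP")
        report["biomonitoring"]["anova_tgp_thep_ratio"] = {"F": f_stat, "p": p_val}

    # --- sensitivity --------------------------------------------------------
    if "THEP" in profiles:
        report["sensitivity"]["thep_inhalation_omission_factor"] = (
            route_omission_factor(
                profiles["THEP"],
                "inhalation",
                n_iter=config.n_iter,
                seed=derive_seed(config.seed, "mc:THEP"),
            )
        )
    report["sensitivity"]["half_life_ratio_6_over_4_1"] = 6.0 / 4.1
    if {"TGP", "THEP"} <= set(uptakes):
        report["sensitivity"]["thep_to_tgp_median_uptake_ratio"] = float(
            np.median(uptakes["THEP"].total) / np.median(uptakes["TGP"].total)
        )
    if {"NGP", "NHEP"} <= set(uptakes):
        report["sensitivity"]["nhep_to_ngp_median_uptake_ratio"] = float(
            np.median(uptakes["NHEP"].total) / np.median(uptakes["NGP"].total)
        )

    if config.output_dir:
        _write_outputs(Path(config.output_dir), report, uptakes)
    log.info("pipeline done")
    return report


def _write_outputs(
    outdir: Path, report: dict, uptakes: Mapping[str, UptakeDistribution]
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    frames = []
    for pop, dist in uptakes.items():
        df = dist.samples.copy()
        df.insert(0, "population", pop)
        df.insert(1, "iteration", np.arange(len(df)))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "uptake_samples.csv", index=False)
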