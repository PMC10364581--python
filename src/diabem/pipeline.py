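"""End-to-end synthetic analysis: simulate → estimate → burden → attribute → forecast.

This module wires the stage modules together exactly as a full analysis
would run them, on a synthetic world:

1. simulate survey prevalence under several case definitions and death
   counts with partially unspecified type coding;
2. crosswalk alternate-definition datapoints onto the reference definition
   (least-trimmed-squares ratios);
3. redistribute unspecified deaths to type 1 / type 2 with the log-linear
   type-split model (under-15 deaths all type 1);
4. fit illness-death-consistent rates per location-sex at a set of
   estimation years (remission capped at 1%/yr for total diabetes, zero
   for type 1), with bootstrap draws at the anchor years; type 2
   prevalence is total minus type 1 at draw level;
5. compute draw-level YLLs, YLDs, DALYs, crude and age-standardised rates;
6. compute PAFs and attributable DALYs for the 16-risk registry, plus the
   multiplicative all-risk aggregate;
7. fit the covariate-driven logit forecasting models (SDI for type 1,
   mean BMI for type 2), project to 2050, intercept-shift onto the 2021
   estimates, and convert to case counts.

Every quantity keeps its draws until summarised; diagnostics (conservation
errors, clamp counts, anchoring error) are collected along the way.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import cod, crosswalk, forecast as forecast_mod, risks as risks_mod
from .containers import DrawSet
from .epi import assign_under15_to_type1, fit_rates, subtract_type1
from .reporting import make_draws, summarise
from .world import SEXES, WorldBundle, WorldConfig, make_world, \
    simulate_death_data, simulate_prevalence_surveys

logger = logging.getLogger(__name__)

DEFAULT_FIT_YEARS = (1990, 2000, 2010, 2021)
DEFAULT_ANCHOR_YEARS = (1990, 2021)
DEATH_DRAW_SD = 0.05  # log-space sd for death-count parameter uncertainty
PAF_DRAW_SD = 0.35  # logit-space sd for PAF parameter uncertainty


@dataclass
class PipelineResult:
    world: WorldBundle
    definition_ratios: dict
    type_split_model: object
    prevalence_estimates: dict  # (cause, year) -> DrawSet over (location, age, sex)
    estimate_history: pd.DataFrame  # cause, location, age_start, sex, year, value
    deaths: pd.DataFrame  # redistributed
    dalys: dict  # (cause, year) -> DrawSet
    as_rates: dict  # summaries of age-standardised rates
    pafs: dict  # name -> DrawSet (cause type2, year 2021) and 'combined'
    forecasts: dict  # cause -> prevalence frame through 2050; 'counts' frames
    diagnostics: dict = field(default_factory=dict)
    headline: dict = field(default_factory=dict)


def _prevalence_drawset(world, fits, cause, year, n_draws) -> DrawSet:
    """Collect per-stratum bootstrap draws into one DrawSet over the grid."""
    rows, draws = [], []
    edges = world.config.age_edges
    for loc in world.locations:
        for sex in SEXES:
            fit = fits[(cause, loc, sex, year)]
            for k in range(len(edges) - 1):
                rows.append((loc, edges[k], edges[k + 1], sex, year))
                draws.append(fit.prevalence_draws[:, k])
    index = pd.DataFrame(rows, columns=["location", "age_start", "age_end", "sex", "year"])
    return DrawSet(index, np.asarray(draws))


def _population_at(world, year) -> pd.DataFrame:
    pop = world.population
    return pop[pop["year"] == year].reset_index(drop=True)


def _align_population(index: pd.DataFrame, world) -> pd.DataFrame:
    keys = ["location", "age_start", "age_end", "sex", "year"]
    merged = index.merge(world.population, on=keys, how="left")
    if merged["value"].isna().any():
        raise ValueError("population missing for some estimate cells")
    return merged


def run_pipeline(
    config: WorldConfig | None = None,
    *,
    seed: int | None = None,
    fit_years=DEFAULT_FIT_YEARS,
    anchor_years=DEFAULT_ANCHOR_YEARS,
) -> PipelineResult:
    """Run the full synthetic analysis chain and return all stage outputs."""
    if config is None:
        config = WorldConfig()
    if seed is not None:
        config = WorldConfig(**{**config.__dict__, "seed": seed})
    n_draws = config.n_draws
    rng = np.random.default_rng(config.seed + 900)
    world = make_world(config)
    edges = config.age_edges
    n_age = len(edges) - 1
    diagnostics = {}

    # ---- 1. observations -------------------------------------------------
    definitions = list(config.definition_log_ratios)
    surveys = simulate_prevalence_surveys(
        world, definitions, noise=config.survey_noise, years=fit_years
    )
    type1_data = simulate_prevalence_surveys(
        world, [crosswalk.REFERENCE_DEFINITION], noise=config.type1_noise,
        outlier_rate=0.0, years=fit_years, cause="type1",
        seed=config.seed + 211,
    )
    u_by_loc = {
        loc: float(np.clip(config.unspecified_death_fraction
                           + rng.uniform(-0.3, 0.3), 0.05, 0.95))
        for loc in world.locations
    }
    death_obs = simulate_death_data(world, u_by_loc)

    # ---- 2. crosswalk ----------------------------------------------------
    keys = ["location", "age_start", "age_end", "sex", "year"]
    ref_obs = surveys[surveys["definition"] == crosswalk.REFERENCE_DEFINITION]
    pair_frames = []
    for d in definitions:
        if d == crosswalk.REFERENCE_DEFINITION:
            continue
        alt = surveys[surveys["definition"] == d]
        merged = ref_obs.merge(alt, on=keys, suffixes=("_ref", "_alt"))
        ok = (merged["value_ref"] > 0) & (merged["value_alt"] > 0)
        pair_frames.append(pd.DataFrame({
            "definition": d,
            "ref_value": merged.loc[ok, "value_ref"],
            "alt_value": merged.loc[ok, "value_alt"],
        }))
    pairs = pd.concat(pair_frames, ignore_index=True)
    ratios = crosswalk.estimate_definition_ratios(pairs, trim_fraction=0.10)
    adjusted = crosswalk.adjust_datapoints(surveys, ratios)
    adjusted["se"] = adjusted["se"].clip(lower=1e-4)
    type1_data = type1_data.copy()
    type1_data["se"] = type1_data["se"].clip(lower=1e-4)

    # ---- 3. death redistribution ----------------------------------------
    obesity = world.covariates["obesity"]
    training = cod.select_training_rows(death_obs, obesity)
    diagnostics["n_training_rows"] = len(training)
    split_model = cod.fit_type_split(training)
    deaths = cod.redistribute_unspecified(death_obs, split_model, obesity)
    cons_err = np.max(np.abs(
        (deaths["type1"] + deaths["type2"]).to_numpy() - death_obs["total"].to_numpy()
    ))
    diagnostics["death_conservation_max_abs_err"] = float(cons_err)

    # ---- 4. consistency fits --------------------------------------------
    pop = world.population
    m_tab = world.background_mortality
    fits = {}
    for loc in world.locations:
        for sex in SEXES:
            m_curve = (
                m_tab[(m_tab["location"] == loc) & (m_tab["sex"] == sex)]
                .sort_values("age_start")["value"].to_numpy()
            )
            for year in fit_years:
                cell = (
                    (deaths["location"] == loc) & (deaths["sex"] == sex)
                    & (deaths["year"] == year)
                )
                d_cell = deaths[cell].sort_values("age_start")
                p_cell = pop[
                    (pop["location"] == loc) & (pop["sex"] == sex)
                    & (pop["year"] == year)
                ].sort_values("age_start")["value"].to_numpy()
                csmr_total = (d_cell["type1"] + d_cell["type2"]).to_numpy() / p_cell
                csmr_type1 = d_cell["type1"].to_numpy() / p_cell
                is_anchor = year in anchor_years
                data_tot = adjusted[
                    (adjusted["location"] == loc) & (adjusted["sex"] == sex)
                    & (adjusted["year"] == year)
                ][["age_start", "value", "se"]]
                fits[("total", loc, sex, year)] = fit_rates(
                    data_tot, csmr_total, edges, m_curve,
                    remission_cap=0.01, smoothness=1e-2, maxiter=120,
                    profile_remission=is_anchor,
                    n_draws=n_draws if is_anchor else 0,
                    seed=int(rng.integers(2**31)),
                )
                data_t1 = type1_data[
                    (type1_data["location"] == loc) & (type1_data["sex"] == sex)
                    & (type1_data["year"] == year)
                ][["age_start", "value", "se"]]
                fits[("type1", loc, sex, year)] = fit_rates(
                    data_t1, csmr_type1, edges, m_curve,
                    no_remission=True, smoothness=1e-2, maxiter=120,
                    n_draws=n_draws if is_anchor else 0,
                    seed=int(rng.integers(2**31)),
                )

    # draw-level prevalence at anchor years; type 2 by subtraction
    prevalence_estimates = {}
    clamp_counts = {}
    for year in anchor_years:
        total_ds = _prevalence_drawset(world, fits, "total", year, n_draws)
        type1_ds = _prevalence_drawset(world, fits, "type1", year, n_draws)
        type1_ds = assign_under15_to_type1(total_ds, type1_ds)
        type2_ds, n_clamped = subtract_type1(total_ds, type1_ds)
        clamp_counts[year] = n_clamped
        prevalence_estimates[("total", year)] = total_ds
        prevalence_estimates[("type1", year)] = type1_ds
        prevalence_estimates[("type2", year)] = type2_ds
    diagnostics["subtraction_clamped_draw_cells"] = clamp_counts

    # point-estimate history for forecasting (logit-linear in year between fits)
    hist_rows = []
    fit_years_arr = np.asarray(fit_years, dtype=float)
    all_years = np.arange(config.year_start, config.year_end + 1)
    for loc in world.locations:
        for sex in SEXES:
            p_tot = np.array([fits[("total", loc, sex, y)].bundle.prevalence
                              for y in fit_years])
            p_t1 = np.array([fits[("type1", loc, sex, y)].bundle.prevalence
                             for y in fit_years])
            young = edges[:-1] < 15.0
            p_t1[:, young] = p_tot[:, young]
            p_t2 = np.maximum(p_tot - p_t1, 0.0)
            for cause, mat in (("total", p_tot), ("type1", p_t1), ("type2", p_t2)):
                logit = np.log(np.clip(mat, 1e-6, 1 - 1e-6)
                               / (1 - np.clip(mat, 1e-6, 1 - 1e-6)))
                for k in range(n_age):
                    interp = np.interp(all_years, fit_years_arr, logit[:, k])
                    vals = 1.0 / (1.0 + np.exp(-interp))
                    for y, v in zip(all_years, vals):
                        hist_rows.append((cause, loc, edges[k], edges[k + 1],
                                          sex, int(y), float(v)))
    estimate_history = pd.DataFrame(
        hist_rows,
        columns=["cause", "location", "age_start", "age_end", "sex", "year", "value"],
    )

    # ---- 5. burden accounting -------------------------------------------
    dalys = {}
    yll_store, yld_store, death_ds_store = {}, {}, {}
    deaths_draw_seed = int(rng.integers(2**31))
    for year in anchor_years:
        d_year = deaths[deaths["year"] == year].sort_values(
            ["location", "sex", "age_start"]).reset_index(drop=True)
        for cause in ("total", "type1", "type2"):
            if cause == "total":
                counts = (d_year["type1"] + d_year["type2"]).to_numpy()
            else:
                counts = d_year[cause].to_numpy()
            index = d_year[["location", "age_start", "age_end", "sex", "year"]]
            death_draws = make_draws(
                np.maximum(counts, 1e-9), DEATH_DRAW_SD, n=n_draws,
                seed=deaths_draw_seed + year, family="lognormal",
            )
            death_ds = DrawSet(index, death_draws)
            yll = burden_mod.compute_yll(death_ds, world.life_table)
            prev = prevalence_estimates[(cause, year)]
            prev_pop = _align_population(prev.index, world)
            sequelae = [
                burden_mod.Sequela(name, world.disability_weights[name],
                                   world.sequela_splits[name])
                for name in world.disability_weights
            ]
            # prevalence and death grids are ordered differently; re-sort
            order = prev.index.sort_values(
                ["location", "sex", "age_start"]).index.to_numpy()
            prev_sorted = DrawSet(prev.index.iloc[order], prev.draws[order])
            prev_pop_sorted = _align_population(prev_sorted.index, world)
            yld = burden_mod.compute_yld(
                prev_sorted, sequelae, prev_pop_sorted,
                background_ylds_per_capita=world.background_yld_per_capita,
            )
            daly = burden_mod.compute_daly(yll, yld)
            dalys[(cause, year)] = daly
            yll_store[(cause, year)] = yll
            yld_store[(cause, year)] = yld
            death_ds_store[(cause, year)] = death_ds

    # standard population from the 2019 grid and age-standardised rates
    pop_2019 = _population_at(world, 2019)
    std = burden_mod.build_standard_population(
        pop_2019.groupby(["location", "age_start"], as_index=False)["value"].sum()
    )
    as_rates = {}
    for (cause, year), daly in dalys.items():
        pop_year = _align_population(daly.index, world)
        daly_rate = burden_mod.rate_per_100k(daly, pop_year)
        as_daly = burden_mod.age_standardise(
            daly_rate, std
        ).aggregate(over=["location", "sex", "year"])
        # population-weighted age-specific rates, then standard weights:
        # aggregate counts and population over locations/sexes first
        daly_by_age = daly.aggregate(over=["location", "sex"])
        pop_by_age = pop_year.groupby(["age_start", "age_end"], as_index=False)["value"].sum()
        daly_by_age_rate = burden_mod.rate_per_100k(
            daly_by_age, daly_by_age.index.merge(pop_by_age, on=["age_start", "age_end"])
        )
        as_rates[(cause, year, "daly")] = summarise(
            burden_mod.age_standardise(daly_by_age_rate, std).draws.ravel()
        )
        prev = prevalence_estimates[(cause, year)]
        pop_prev = _align_population(prev.index, world)
        prev_counts = DrawSet(prev.index, prev.draws * pop_prev["value"].to_numpy()[:, None])
        prev_by_age = prev_counts.aggregate(over=["location", "sex"])
        pba = prev_by_age.index.merge(
            pop_prev.groupby(["age_start", "age_end"], as_index=False)["value"].sum(),
            on=["age_start", "age_end"],
        )
        prev_rate = DrawSet(prev_by_age.index,
                            prev_by_age.draws / pba["value"].to_numpy()[:, None])
        as_rates[(cause, year, "prevalence")] = summarise(
            burden_mod.age_standardise(prev_rate, std).draws.ravel()
        )

    # ---- 6. risk attribution --------------------------------------------
    paf_seed = int(rng.integers(2**31))
    pafs = {}
    bmi_tab = world.covariates["bmi"]
    type2_dalys_2021 = dalys[("type2", 2021)]
    paf_index = pd.DataFrame({"location": ["global"]})
    per_risk_pafs = []
    bmi_pafs_by_year = {}
    for risk in world.risk_factors:
        if "type2" not in risk.applies_to:
            continue
        if risk.name == "high body-mass index":
            for year in anchor_years:
                # exposure per stratum from the mean-BMI covariate, population-weighted
                bmi_year = bmi_tab[(bmi_tab["year"] == year)
                                   & (bmi_tab["age_start"] >= 25)]
                pop_year = _align_population(
                    bmi_year[["location", "age_start", "age_end", "sex", "year"]], world
                )
                w = pop_year["value"].to_numpy()
                mean_bmi = float(np.average(bmi_year["value"].to_numpy(), weights=w))
                exposure = risks_mod.ExposureDistribution.normal(
                    mean_bmi, 4.0, risk.curve.grid
                )
                point = risks_mod.paf_for_risk(risk, exposure)
                draws = make_draws(point, PAF_DRAW_SD, n=n_draws,
                                   seed=paf_seed + year, family="logit-normal")
                bmi_pafs_by_year[year] = DrawSet(paf_index, draws.reshape(1, -1))
            pafs[risk.name] = bmi_pafs_by_year[2021]
            per_risk_pafs.append(pafs[risk.name])
        else:
            point = risks_mod.paf_for_risk(risk)
            name_tag = zlib.crc32(risk.name.encode()) % 10000
            draws = make_draws(point, PAF_DRAW_SD, n=n_draws,
                               seed=paf_seed + name_tag,
                               family="logit-normal")
            pafs[risk.name] = DrawSet(paf_index, draws.reshape(1, -1))
            per_risk_pafs.append(pafs[risk.name])
    combined = risks_mod.aggregate_pafs(per_risk_pafs)
    pafs["combined"] = combined
    daly_total_t2 = DrawSet(paf_index, type2_dalys_2021.total().reshape(1, -1))
    attributable = risks_mod.attributable_burden(combined, daly_total_t2)
    diagnostics["attributable_le_total"] = bool(
        np.all(attributable.draws <= daly_total_t2.draws + 1e-9)
    )
    _, bmi_change = risks_mod.paf_percentage_change(
        bmi_pafs_by_year[anchor_years[0]], bmi_pafs_by_year[2021]
    )

    # ---- 7. forecasting --------------------------------------------------
    sdi = world.covariates["sdi"].copy()
    bmi_cov = bmi_tab.copy()
    hist = estimate_history[estimate_history["year"] <= config.year_end]
    models = {}
    shifted = {}
    counts = {}
    pop_fc = world.population
    anchor_2021 = {}
    for cause, cov, name in (("type1", sdi, "SDI"), ("type2", bmi_cov, "BMI")):
        h = hist[hist["cause"] == cause].drop(columns="cause")
        model = forecast_mod.fit_forecast_model(h, cov, covariate_name=name)
        cov_fc = cov.copy()
        if "age_start" not in cov_fc.columns:
            # SDI is a location-year index; expand to the stratum grid
            strata = h[["location", "age_start", "age_end", "sex"]].drop_duplicates()
            cov_fc = strata.merge(cov_fc, on="location")
        proj = forecast_mod.project(model, cov_fc)
        est_2021 = h[h["year"] == config.year_end]
        anchored = forecast_mod.intercept_shift(proj, est_2021,
                                                anchor_year=config.year_end)
        models[cause] = model
        shifted[cause] = anchored
        counts[cause] = forecast_mod.forecast_counts(anchored, pop_fc)
        anchor_check = anchored[anchored["year"] == config.year_end].merge(
            est_2021.rename(columns={"value": "est"}),
            on=["location", "age_start", "sex"],
        )
        anchor_2021[cause] = float(
            np.max(np.abs(anchor_check["value"] - anchor_check["est"]))
        )
    diagnostics["anchor_max_abs_err"] = anchor_2021
    # total = type1 + type2 per cell
    k = ["location", "age_start", "age_end", "sex", "year"]
    tot = shifted["type1"].merge(shifted["type2"], on=k, suffixes=("_1", "_2"))
    tot["value"] = (tot["value_1"] + tot["value_2"]).clip(upper=1.0)
    shifted["total"] = tot[k + ["value"]]
    counts["total"] = forecast_mod.forecast_counts(shifted["total"], pop_fc)

    # ---- headline summaries ----------------------------------------------
    pop21 = _align_population(prevalence_estimates[("total", 2021)].index, world)
    cases_2021 = (prevalence_estimates[("total", 2021)].draws
                  * pop21["value"].to_numpy()[:, None]).sum(axis=0)
    cases_2050 = counts["total"].loc[counts["total"]["year"] == config.forecast_end,
                                     "cases"].sum()
    # age-standardised prevalence forecast for 2050
    fc50 = shifted["total"][shifted["total"]["year"] == config.forecast_end]
    pop50 = _align_population(fc50[k], world)
    c50 = fc50["value"].to_numpy() * pop50["value"].to_numpy()
    fc50_counts = DrawSet(fc50[k].reset_index(drop=True), c50.reshape(-1, 1))
    by_age = fc50_counts.aggregate(over=["location", "sex"])
    pop50_age = pop50.groupby(["age_start", "age_end"], as_index=False)["value"].sum()
    pa = by_age.index.merge(pop50_age, on=["age_start", "age_end"])
    rate50 = DrawSet(by_age.index, by_age.draws / pa["value"].to_numpy()[:, None])
    as_prev_2050 = float(burden_mod.age_standardise(rate50, std).draws.ravel()[0])

    headline = {
        "cases_2021": summarise(cases_2021),
        "cases_2050": float(cases_2050),
        "as_prevalence_2021": as_rates[("total", 2021, "prevalence")],
        "as_prevalence_2050": as_prev_2050,
        "as_daly_rate_2021": as_rates[("total", 2021, "daly")],
        "daly_count_2021": summarise(dalys[("total", 2021)].total()),
        "yll_count_2021": summarise(yll_store[("total", 2021)].total()),
        "yld_count_2021": summarise(yld_store[("total", 2021)].total()),
        "type2_case_share_2021": summarise(
            prevalence_estimates[("type2", 2021)].draws.sum(axis=0)
            / np.maximum(prevalence_estimates[("total", 2021)].draws.sum(axis=0), 1e-12)
        ),
        "bmi_paf_2021": summarise(pafs["high body-mass index"].draws.ravel()),
        "combined_paf_2021": summarise(combined.draws.ravel()),
        "bmi_paf_pct_change": bmi_change,
        "attributable_dalys_2021": summarise(attributable.draws.ravel()),
        "beta1_type1_sdi": models["type1"].beta1,
        "beta1_type2_bmi": models["type2"].beta1,
    }

    # DALY = YLL + YLD additivity check across everything computed
    max_rel = 0.0
    for key, daly in dalys.items():
        resid = np.abs(daly.draws - yll_store[key].draws - yld_store[key].draws)
        denom = np.maximum(np.abs(daly.draws), 1e-12)
        max_rel = max(max_rel, float((resid / denom).max()))
    diagnostics["daly_additivity_max_rel_err"] = max_rel
    diagnostics["paf_range"] = (
        float(min(p.draws.min() for p in pafs.values())),
        float(max(p.draws.max() for p in pafs.values())),
    )

    return PipelineResult(
        world=world,
        definition_ratios=ratios,
        type_split_model=split_model,
        prevalence_estimates=prevalence_estimates,
        estimate_history=estimate_history,
        deaths=deaths,
        dalys=dalys,
        as_rates=as_rates,
        pafs=pafs,
        forecasts={"prevalence": shifted, "counts": counts, "models": models},
        diagnostics=diagnostics,
        headline=headline,
    )
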