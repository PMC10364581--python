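"""Synthetic epidemiological world: self-consistent truth plus noisy observations.

The generator builds a small multi-location "world" with the statistical
structure a burden-of-disease analysis assumes, so that every downstream
stage (crosswalking, death redistribution, consistency fitting, DALY
accounting, risk attribution, forecasting) can be exercised and its
recovery of the embedded truth tested without any external data.

Truth is constructed bottom-up: type-specific incidence, remission and
excess-mortality age curves are drawn per location and sex (linked to
obesity and the socio-demographic index so the covariate-driven structure
the forecasting equations assume is actually present), and the true
prevalence of each diabetes type is, by construction, the illness-death
solution of those rates. Observations are then simulated on top of the
truth: prevalence surveys under multiple case definitions with binomial
sampling noise and optional gross outliers, and death counts with a
configurable fraction of deaths coded to unspecified type.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .epi import RateBundle, solve_illness_death
from .risks import ExposureDistribution, RelativeRiskCurve, RiskFactor

__all__ = ["WorldConfig", "WorldBundle", "LifeTable", "make_world",
           "simulate_prevalence_surveys", "simulate_death_data"]


class ConfigurationError(ValueError):
    """Raised when a world configuration violates its invariants."""


SEXES = ("female", "male")

#: the four modelled long-term consequences of diabetes, with severity
#: weights on the 0 (healthy) – 1 (death-equivalent) scale and the
#: proportion of prevalent cases in each state (synthetic values; mutually
#: exclusive splits, remainder uncomplicated and contributing no YLDs)
DEFAULT_DISABILITY_WEIGHTS = {
    "neuropathy": 0.133,
    "diabetic foot": 0.165,
    "lower limb amputation": 0.164,
    "vision loss due to retinopathy": 0.184,
}
DEFAULT_SEQUELA_SPLITS = {
    "neuropathy": 0.20,
    "diabetic foot": 0.06,
    "lower limb amputation": 0.02,
    "vision loss due to retinopathy": 0.04,
}


@dataclass
class WorldConfig:
    """Tunable description of the synthetic world.

    ``survey_noise`` is the target standard error of one survey prevalence
    datapoint (sampling is binomial at the implied effective sample size);
    ``outlier_rate`` is the fraction of datapoints replaced by gross
    outliers (truth multiplied by 0.2 or 5), creating the contamination
    regime the trimmed crosswalk estimator is designed for.
    """

    n_locations: int = 5
    age_group_edges: tuple = tuple(float(a) for a in range(0, 100, 5)) + (100.0,)
    year_start: int = 1990
    year_end: int = 2021
    forecast_end: int = 2050
    n_draws: int = 100
    seed: int = 0
    survey_noise: float = 0.02
    #: target SE for type 1 datapoints (registry/claims-like sources are far
    #: more precise than household surveys, and type 1 prevalence is ~100×
    #: rarer than total diabetes)
    type1_noise: float = 0.0002
    outlier_rate: float = 0.05
    unspecified_death_fraction: float = 0.55
    remission_type2: float = 0.005  # per year; under the 1%/yr cap
    #: true multiplicative shift of each alternate case definition relative
    #: to the reference (fasting plasma glucose >= 7 mmol/L or medication),
    #: stored as log-ratios
    definition_log_ratios: dict = field(
        default_factory=lambda: {
            "fpg_ref": 0.0,
            "hba1c": -0.16,
            "ogtt": 0.10,
            "ppg": 0.18,
        }
    )
    #: Eq-style true slopes used to link covariates into the incidence truth
    beta1_sdi_type1: float = 1.5  # logit-prevalence units per SDI unit
    beta1_bmi_type2: float = 0.08  # logit-prevalence units per kg/m^2
    type1_incidence_range: tuple = (6e-5, 2.0e-4)  # peak incidence per person-year
    type2_incidence_range: tuple = (0.008, 0.02)  # adult plateau per person-year
    disability_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_DISABILITY_WEIGHTS)
    )
    sequela_splits: dict = field(default_factory=lambda: dict(DEFAULT_SEQUELA_SPLITS))

    def __post_init__(self):
        if self.n_locations < 1:
            raise ConfigurationError("n_locations: need at least one location")
        edges = np.asarray(self.age_group_edges, dtype=float)
        if len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ConfigurationError("age_group_edges must be strictly increasing")
        for name in ("survey_noise",):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("outlier_rate", "unspecified_death_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a proportion in [0, 1]")
        if not 0.0 <= self.remission_type2 <= 0.01:
            raise ConfigurationError(
                "remission_type2 must respect the 1%/yr remission ceiling"
            )
        for name, w in self.disability_weights.items():
            if not 0.0 < w < 1.0:
                raise ConfigurationError(f"disability weight for {name} must be in (0,1)")
        splits = np.array(list(self.sequela_splits.values()))
        if np.any(splits < 0) or splits.sum() > 1.0:
            raise ConfigurationError("sequela splits must be >= 0 and sum to <= 1")
        if self.year_end < self.year_start + 2:
            raise ConfigurationError("need at least three years of history")

    @property
    def age_edges(self) -> np.ndarray:
        return np.asarray(self.age_group_edges, dtype=float)

    @property
    def history_years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def all_years(self) -> np.ndarray:
        return np.arange(self.year_start, self.forecast_end + 1)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "age_group_edges" in raw:
            raw["age_group_edges"] = tuple(float(a) for a in raw["age_group_edges"])
        for key in ("type1_incidence_range", "type2_incidence_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["age_group_edges"] = list(self.age_group_edges)
        for key in ("type1_incidence_range", "type2_incidence_range"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class LifeTable:
    """Remaining life expectancy (years) as a function of exact age."""

    ages: np.ndarray
    ex: np.ndarray

    def remaining(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if np.any(age < self.ages[0]) or np.any(age > self.ages[-1]):
            raise ValueError(
                f"age outside life-table coverage [{self.ages[0]}, {self.ages[-1]}]"
            )
        return np.interp(age, self.ages, self.ex)


@dataclass
class WorldBundle:
    """Truth plus the ingredients every downstream stage needs."""

    config: WorldConfig
    locations: list
    population: pd.DataFrame  # location, age_start, age_end, sex, year, value
    covariates: dict  # name -> tidy frame ('sdi', 'obesity', 'bmi')
    true_prevalence: pd.DataFrame  # cause, location, age_start, age_end, sex, year, value
    true_csmr: pd.DataFrame
    true_incidence: pd.DataFrame
    true_excess: pd.DataFrame
    background_mortality: pd.DataFrame  # location, age_start, sex, value (per year rate)
    life_table: LifeTable
    disability_weights: dict
    sequela_splits: dict
    risk_factors: list  # list of risks.RiskFactor
    background_yld_per_capita: float = 0.10

    def get_rate_bundle(self, cause: str, location, sex: str, year: int) -> RateBundle:
        """Reassemble the true RateBundle for one stratum-year."""
        edges = self.config.age_edges

        def pick(frame):
            sel = frame[
                (frame["cause"] == cause)
                & (frame["location"] == location)
                & (frame["sex"] == sex)
                & (frame["year"] == year)
            ].sort_values("age_start")
            return sel["value"].to_numpy()

        m = self.background_mortality
        m_sel = m[(m["location"] == location) & (m["sex"] == sex)].sort_values("age_start")
        n = len(edges) - 1
        r = (
            np.zeros(n)
            if cause == "type1"
            else np.full(n, self.config.remission_type2)
        )
        i = pick(self.true_incidence)
        p = pick(self.true_prevalence)
        csmr = pick(self.true_csmr)
        f = pick(self.true_excess)
        bundle = RateBundle(
            age_edges=edges,
            incidence=i,
            remission=r,
            excess_mortality=f,
            background_mortality=m_sel["value"].to_numpy(),
            prevalence=p,
            csmr=csmr,
        )
        return bundle

    def truth_table(self, cause: str, measure: str = "prevalence") -> pd.DataFrame:
        frame = {
            "prevalence": self.true_prevalence,
            "csmr": self.true_csmr,
            "incidence": self.true_incidence,
            "excess": self.true_excess,
        }[measure]
        out = frame[frame["cause"] == cause].drop(columns="cause").reset_index(drop=True)
        return out


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_world(config: WorldConfig) -> WorldBundle:
    """Generate a deterministic world from *config* (same seed, same world)."""
    rng = np.random.default_rng(config.seed)
    edges = config.age_edges
    n_age = len(edges) - 1
    ages = edges[:-1]
    mid = (edges[:-1] + edges[1:]) / 2
    years = config.all_years
    n_years = len(years)
    locations = [f"loc_{k:02d}" for k in range(config.n_locations)]

    # ---- population -----------------------------------------------------
    pop_scale = rng.uniform(np.log(2e6), np.log(5e7), config.n_locations)
    pop_scale = np.exp(pop_scale)
    pop_scale[0] = max(pop_scale[0], 8e6)  # ensure a standard-population anchor
    growth = rng.uniform(0.004, 0.018, config.n_locations)
    age_shape = np.exp(-0.025 * mid)
    age_shape = age_shape / age_shape.sum()

    # ---- covariates -----------------------------------------------------
    sdi_base = rng.uniform(0.35, 0.80, config.n_locations)
    sdi_slope = rng.uniform(0.0008, 0.0025, config.n_locations)
    ob_base = rng.uniform(0.08, 0.30, config.n_locations)
    ob_slope = rng.uniform(0.0015, 0.0045, config.n_locations)

    sdi_rows, ob_rows = [], []
    for li, loc in enumerate(locations):
        for yi, y in enumerate(years):
            t = y - config.year_start
            sdi_rows.append((loc, y, float(np.clip(sdi_base[li] + sdi_slope[li] * t, 0.05, 0.95))))
            ob_rows.append((loc, y, float(np.clip(ob_base[li] + ob_slope[li] * t, 0.02, 0.60))))
    sdi = pd.DataFrame(sdi_rows, columns=["location", "year", "value"])
    obesity = pd.DataFrame(ob_rows, columns=["location", "year", "value"])

    # mean BMI per stratum: anchored to obesity, with a mild age profile
    bmi_rows = []
    sex_shift = {"female": 0.3, "male": 0.0}
    ob_map = {(r.location, r.year): r.value for r in obesity.itertuples()}
    age_bump = 3.0 * np.sqrt(np.maximum(mid, 1.0) / 100.0)
    for loc in locations:
        for sex in SEXES:
            for y in years:
                base = 20.5 + 16.0 * ob_map[(loc, y)] + sex_shift[sex]
                for k in range(n_age):
                    bmi_rows.append((loc, ages[k], edges[k + 1], sex, int(y),
                                     float(base + age_bump[k])))
    bmi = pd.DataFrame(
        bmi_rows, columns=["location", "age_start", "age_end", "sex", "year", "value"]
    )

    # ---- background (non-diabetes) mortality ----------------------------
    m_rows = []
    sex_mort = {"female": 1.0, "male": 1.35}
    for li, loc in enumerate(locations):
        level = 4e-4 * rng.uniform(0.8, 1.3)
        for sex in SEXES:
            m_curve = level * sex_mort[sex] * np.exp(0.075 * mid)
            for k in range(n_age):
                m_rows.append((loc, ages[k], edges[k + 1], sex, float(m_curve[k])))
    background_mortality = pd.DataFrame(
        m_rows, columns=["location", "age_start", "age_end", "sex", "value"]
    )

    # ---- true type-specific rate curves ---------------------------------
    i1_peak = rng.uniform(*config.type1_incidence_range, config.n_locations)
    i2_plateau = rng.uniform(*config.type2_incidence_range, config.n_locations)
    sex_i2 = {"female": 1.0, "male": 1.12}
    sex_i1 = {"female": 1.0, "male": 1.05}

    pop_rows = []
    rate_rows = {"incidence": [], "prevalence": [], "csmr": [], "excess": []}

    # batch the ODE solves over (location, sex, year) per cause
    strata = [(li, loc, sex) for li, loc in enumerate(locations) for sex in SEXES]
    for li, loc, sex in strata:
        m_curve = (
            background_mortality[
                (background_mortality["location"] == loc)
                & (background_mortality["sex"] == sex)
            ]
            .sort_values("age_start")["value"]
            .to_numpy()
        )
        i1_base = i1_peak[li] * sex_i1[sex] * (
            np.exp(-(((mid - 12.0) / 14.0) ** 2)) + 0.05
        )
        i2_shape = _logistic((mid - 45.0) / 12.0) * (mid >= 15.0)
        I1 = np.empty((n_years, n_age))
        I2 = np.empty((n_years, n_age))
        F1 = np.empty((n_years, n_age))
        F2 = np.empty((n_years, n_age))
        for yi, y in enumerate(years):
            s = sdi.loc[(sdi["location"] == loc) & (sdi["year"] == y), "value"].iloc[0]
            ob = ob_map[(loc, y)]
            # covariate links: type 1 incidence rises with SDI (registration
            # and survival), type 2 incidence with obesity
            I1[yi] = i1_base * (0.6 + config.beta1_sdi_type1 * 0.4 * s)
            I2[yi] = i2_plateau[li] * sex_i2[sex] * i2_shape * (
                0.45 + 2.2 * ob
            )
            F1[yi] = 0.012 * (1.7 - s) * (1.0 + mid / 150.0)
            F2[yi] = (0.004 + 0.00018 * mid) * (1.6 - s)
        R1 = np.zeros_like(I1)
        R2 = np.full_like(I2, config.remission_type2)
        M = np.broadcast_to(m_curve, I1.shape)
        sol1 = solve_illness_death(I1, R1, F1, M, edges)
        sol2 = solve_illness_death(I2, R2, F2, M, edges)
        for yi, y in enumerate(years):
            t = y - config.year_start
            pop_cell = pop_scale[li] * (1 + growth[li]) ** t * age_shape / 2.0
            for k in range(n_age):
                pop_rows.append((loc, ages[k], edges[k + 1], sex, int(y), pop_cell[k]))
            for cause, sol, inc, exc in (("type1", sol1, I1, F1), ("type2", sol2, I2, F2)):
                p = sol.prevalence[yi]
                c = sol.csmr[yi]
                ex = exc[yi]
                for k in range(n_age):
                    rate_rows["incidence"].append(
                        (cause, loc, ages[k], edges[k + 1], sex, int(y), inc[yi][k])
                    )
                    rate_rows["prevalence"].append(
                        (cause, loc, ages[k], edges[k + 1], sex, int(y), p[k])
                    )
                    rate_rows["csmr"].append(
                        (cause, loc, ages[k], edges[k + 1], sex, int(y), c[k])
                    )
                    rate_rows["excess"].append(
                        (cause, loc, ages[k], edges[k + 1], sex, int(y), ex[k])
                    )

    cols = ["cause", "location", "age_start", "age_end", "sex", "year", "value"]
    frames = {k: pd.DataFrame(v, columns=cols) for k, v in rate_rows.items()}

    # total diabetes: rates and prevalence are the type sums (prevalence of
    # the two types is additive because the states are disjoint and rare)
    totals = {}
    for measure in ("incidence", "prevalence", "csmr"):
        frame = frames[measure]
        t1 = frame[frame["cause"] == "type1"].reset_index(drop=True)
        t2 = frame[frame["cause"] == "type2"].reset_index(drop=True)
        tot = t1.copy()
        tot["cause"] = "total"
        tot["value"] = t1["value"].to_numpy() + t2["value"].to_numpy()
        if measure == "prevalence":
            tot["value"] = tot["value"].clip(upper=1.0)
        totals[measure] = tot
    tot_ex = totals["csmr"].copy()
    p_tot = totals["prevalence"]["value"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tot_ex["value"] = np.where(
            p_tot > 0, tot_ex["value"].to_numpy() / np.where(p_tot > 0, p_tot, 1.0), 0.0
        )
    totals["excess"] = tot_ex
    for measure in frames:
        frames[measure] = pd.concat(
            [frames[measure], totals[measure]], ignore_index=True
        )

    population = pd.DataFrame(
        pop_rows, columns=["location", "age_start", "age_end", "sex", "year", "value"]
    )

    lt_ages = np.arange(0.0, 111.0)
    life_table = LifeTable(ages=lt_ages, ex=np.maximum((88.9 - lt_ages) * 0.97, 2.0))

    risk_factors = default_risk_registry(rng)

    return WorldBundle(
        config=config,
        locations=locations,
        population=population,
        covariates={"sdi": sdi, "obesity": obesity, "bmi": bmi},
        true_prevalence=frames["prevalence"],
        true_csmr=frames["csmr"],
        true_incidence=frames["incidence"],
        true_excess=frames["excess"],
        background_mortality=background_mortality,
        life_table=life_table,
        disability_weights=dict(config.disability_weights),
        sequela_splits=dict(config.sequela_splits),
        risk_factors=risk_factors,
    )


# ---------------------------------------------------------------------------
# observation simulators
# ---------------------------------------------------------------------------


def simulate_prevalence_surveys(
    world: WorldBundle,
    definitions,
    noise: float,
    outlier_rate: float | None = None,
    years=None,
    cause: str = "total",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate survey prevalence datapoints under the given case definitions.

    Each datapoint is the stratum's true prevalence shifted by the
    definition's true log-ratio, optionally replaced by a gross outlier
    (×0.2 or ×5) at rate ``outlier_rate``, then sampled binomially at the
    effective sample size implied by ``noise`` (the target standard error).
    ``noise=0`` returns the shifted truth exactly with zero standard error.
    """
    known = world.config.definition_log_ratios
    for d in definitions:
        if d not in known:
            raise ValueError(
                f"unknown case definition {d!r}; known definitions: {sorted(known)}"
            )
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if outlier_rate is None:
        outlier_rate = world.config.outlier_rate
    if years is None:
        years = world.config.history_years
    rng = np.random.default_rng(world.config.seed + 101 if seed is None else seed)

    truth = world.truth_table(cause, "prevalence")
    truth = truth[truth["year"].isin(np.asarray(years))].reset_index(drop=True)
    rows = []
    for d in definitions:
        shift = np.exp(known[d])
        base = np.clip(truth["value"].to_numpy() * shift, 0.0, 1.0)
        n = len(base)
        is_outlier = rng.random(n) < outlier_rate
        factor = np.where(rng.random(n) < 0.5, 0.2, 5.0)
        contaminated = np.where(is_outlier, np.clip(base * factor, 0.0, 1.0), base)
        if noise > 0:
            n_eff = np.maximum(
                10, np.round(contaminated * (1 - contaminated) / noise**2)
            ).astype(int)
            obs = rng.binomial(n_eff, np.clip(contaminated, 0.0, 1.0)) / n_eff
            se = np.sqrt(np.maximum(obs * (1 - obs), 1e-8) / n_eff)
        else:
            obs = contaminated
            se = np.zeros(n)
        block = truth[["location", "age_start", "age_end", "sex", "year"]].copy()
        block["definition"] = d
        block["value"] = obs
        block["se"] = se
        block["is_outlier"] = is_outlier
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def simulate_death_data(
    world: WorldBundle, unspecified_fraction, seed: int | None = None
) -> pd.DataFrame:
    """Deaths per demographic cell by coded type (type1 | type2 | unspecified).

    ``unspecified_fraction`` may be a scalar or a mapping location → scalar.
    Deaths are real-valued (person-counts need not be integers downstream);
    per cell, coded type 1 + coded type 2 + unspecified equals the true
    total exactly. Deaths under age 15 are all truly type 1 by construction
    of the world's incidence curves.
    """
    if np.isscalar(unspecified_fraction):
        frac_of = {loc: float(unspecified_fraction) for loc in world.locations}
    else:
        frac_of = {loc: float(unspecified_fraction[loc]) for loc in world.locations}
    for loc, u in frac_of.items():
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"unspecified fraction for {loc} must be in [0, 1]")

    pop = world.population.rename(columns={"value": "population"})
    keys = ["location", "age_start", "age_end", "sex", "year"]
    c1 = world.truth_table("type1", "csmr").rename(columns={"value": "csmr1"})
    c2 = world.truth_table("type2", "csmr").rename(columns={"value": "csmr2"})
    merged = pop.merge(c1, on=keys).merge(c2, on=keys)
    d1 = merged["population"] * merged["csmr1"]
    d2 = merged["population"] * merged["csmr2"]
    total = d1 + d2
    u = merged["location"].map(frac_of).to_numpy()
    out = merged[keys].copy()
    out["type1"] = (1 - u) * d1
    out["type2"] = (1 - u) * d2
    out["unspecified"] = u * total
    out["total"] = total
    return out


# ---------------------------------------------------------------------------
# risk-factor registry
# ---------------------------------------------------------------------------

_CATEGORICAL_RISKS = [
    # name, exposed prevalence, relative risk at exposure
    ("smoking", 0.22, 1.45),
    ("second-hand smoke", 0.30, 1.20),
    ("household air pollution from solid fuels", 0.25, 1.25),
    ("high alcohol use", 0.08, 1.15),
    ("diet high in processed meat", 0.30, 1.30),
    ("diet high in sugar-sweetened beverages", 0.35, 1.28),
    ("diet high in red meat", 0.40, 1.22),
    ("diet low in fruits", 0.45, 1.18),
    ("diet low in vegetables", 0.40, 1.15),
    ("diet low in whole grains", 0.55, 1.25),
    ("diet low in fibre", 0.50, 1.18),
    ("low physical activity", 0.32, 1.35),
]


def default_risk_registry(rng=None) -> list:
    """The 16 modelled risk factors for diabetes.

    High and low air temperature attach to both diabetes types; all other
    risks to type 2 only. High body-mass index is continuous (its exposure
    distribution is rebuilt per stratum from the world's mean BMI); ambient
    particulate matter is continuous; the remainder are binary exposures.
    """
    risks = []
    bmi_grid = np.linspace(15.0, 45.0, 61)
    bmi_rr = np.where(bmi_grid <= 23.0, 1.0, 1.0 + 0.09 * (bmi_grid - 23.0))
    risks.append(
        RiskFactor(
            name="high body-mass index",
            curve=RelativeRiskCurve(grid=bmi_grid, rr=bmi_rr, units="kg/m^2"),
            tmrel=(20.0, 25.0),
            applies_to=("type2",),
            exposure=None,  # built per stratum from the BMI covariate
        )
    )
    pm_grid = np.linspace(0.0, 100.0, 51)
    pm_rr = 1.0 + 0.004 * pm_grid
    pm_density = np.exp(-((pm_grid - 35.0) ** 2) / (2 * 18.0**2))
    pm_density /= np.trapezoid(pm_density, pm_grid)
    risks.append(
        RiskFactor(
            name="ambient particulate matter pollution",
            curve=RelativeRiskCurve(grid=pm_grid, rr=pm_rr, units="ug/m^3"),
            tmrel=5.0,
            applies_to=("type2",),
            exposure=ExposureDistribution(grid=pm_grid, density=pm_density),
        )
    )
    for name, tmrel_side in (("high air temperature", "upper"),
                             ("low air temperature", "lower")):
        t_grid = np.linspace(-10.0, 35.0, 46)
        if tmrel_side == "upper":
            rr = np.where(t_grid <= 20.0, 1.0, 1.0 + 0.012 * (t_grid - 20.0))
        else:
            rr = np.where(t_grid >= 15.0, 1.0, 1.0 + 0.010 * (15.0 - t_grid))
        density = np.exp(-((t_grid - 18.0) ** 2) / (2 * 8.0**2))
        density /= np.trapezoid(density, t_grid)
        risks.append(
            RiskFactor(
                name=name,
                curve=RelativeRiskCurve(grid=t_grid, rr=rr, units="degC"),
                tmrel=(15.0, 20.0),
                applies_to=("type1", "type2"),
                exposure=ExposureDistribution(grid=t_grid, density=density),
            )
        )
    for name, p_exp, rr in _CATEGORICAL_RISKS:
        risks.append(
            RiskFactor(
                name=name,
                curve=None,
                tmrel="unexposed",
                applies_to=("type2",),
                exposure=ExposureDistribution(
                    categories={"unexposed": 1.0 - p_exp, "exposed": p_exp}
                ),
                categorical_rr={"unexposed": 1.0, "exposed": rr},
            )
        )
    assert len(risks) == 16
    return risks
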