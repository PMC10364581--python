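"""Prevalence forecasting with covariate-driven logit regressions.

Historical prevalence Y for each location l, age a, sex s and year y is
logit-transformed and regressed on a single covariate with one global
slope and a stratum intercept::

    E[logit(Y_{l,a,s,y})] = beta1 * X_{l,a,s,y} + alpha_{l,a,s}

with X the Socio-demographic Index for type 1 diabetes and mean body-mass
index for type 2 diabetes. The intercept alpha is a random effect by
default (REML via a linear mixed model); a fixed-effects (within)
estimator is available behind a flag. Projections are anchored by an
intercept shift in natural (rate) space: the 2021 difference between the
estimated and projected prevalence is added to every forecast year, so
the shifted trajectory passes exactly through the 2021 estimate. Case
counts are forecast prevalence × forecast population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ForecastModel", "fit_forecast_model", "project", "intercept_shift",
           "forecast_counts"]

logger = logging.getLogger(__name__)

_LOGIT_CLAMP = 1e-6
STRATUM_COLS = ["location", "age_start", "sex"]


def _logit(p):
    p = np.clip(p, _LOGIT_CLAMP, 1.0 - _LOGIT_CLAMP)
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ForecastModel:
    """Fitted slope + stratum intercepts, plus anchoring offsets."""

    beta1: float
    alphas: pd.DataFrame  # STRATUM_COLS + 'alpha'
    covariate_name: str
    residual_sd: float
    method: str
    shift_offsets: pd.DataFrame | None = None  # set by intercept_shift
    diagnostics: dict = field(default_factory=dict)


def _merge_covariate(prevalence: pd.DataFrame, covariate: pd.DataFrame) -> pd.DataFrame:
    cov_keys = [c for c in ("location", "age_start", "sex", "year") if c in covariate.columns]
    cov = covariate.rename(columns={"value": "x"})
    drop = [c for c in ("age_end",) if c in cov.columns]
    merged = prevalence.merge(cov.drop(columns=drop), on=cov_keys, how="left")
    if merged["x"].isna().any():
        bad = merged.loc[merged["x"].isna(), ["location", "year"]].drop_duplicates()
        raise ValueError(
            f"covariate missing for {len(bad)} location-years, e.g. "
            f"{bad.head(3).to_dict('records')}"
        )
    return merged


def fit_forecast_model(
    historical_prevalence: pd.DataFrame,
    covariate: pd.DataFrame,
    covariate_name: str,
    method: str = "random",
) -> ForecastModel:
    """Estimate the global slope and stratum intercepts from history.

    ``historical_prevalence`` is a demographic table of prevalence
    (proportion) over at least three years per stratum; ``covariate`` a
    matching table of SDI or mean BMI. ``method="random"`` fits a linear
    mixed model with a random intercept per stratum (REML);
    ``method="fixed"`` uses the exact within-stratum estimator.
    """
    if method not in ("random", "fixed"):
        raise ValueError("method must be 'random' or 'fixed'")
    df = _merge_covariate(historical_prevalence, covariate)
    df = df.copy()
    df["y"] = _logit(df["value"].to_numpy())
    counts = df.groupby(STRATUM_COLS)["year"].nunique()
    if (counts < 3).any():
        bad = counts[counts < 3].index[:3].tolist()
        raise ValueError(f"need >= 3 years of history per stratum; too few in {bad}")
    group = df[STRATUM_COLS].astype(str).agg("|".join, axis=1)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    xc = df.groupby(group.values)["x"].transform("mean").to_numpy()
    within_var = float(np.mean((x - xc) ** 2))
    if within_var < 1e-12:
        raise ValueError(
            "covariate shows no within-stratum variation over time; "
            "the slope is unidentifiable"
        )

    if method == "fixed":
        yc = df.groupby(group.values)["y"].transform("mean").to_numpy()
        beta1 = float(np.sum((x - xc) * (y - yc)) / np.sum((x - xc) ** 2))
        resid = (y - yc) - beta1 * (x - xc)
        strata = df[STRATUM_COLS].drop_duplicates().reset_index(drop=True)
        means = (
            df.assign(g=group.values)
            .groupby(STRATUM_COLS, as_index=False)
            .agg(ybar=("y", "mean"), xbar=("x", "mean"))
        )
        means["alpha"] = means["ybar"] - beta1 * means["xbar"]
        alphas = means[STRATUM_COLS + ["alpha"]]
        residual_sd = float(np.std(resid, ddof=1))
        diagnostics = {"n_obs": len(df), "n_strata": len(strata)}
    else:
        exog = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, exog, groups=group.values)
            res = model.fit(reml=True, method="lbfgs", maxiter=200)
        beta1 = float(res.fe_params[1])
        const = float(res.fe_params[0])
        re = res.random_effects
        strata = df[STRATUM_COLS].drop_duplicates().reset_index(drop=True)
        keys = strata.astype(str).agg("|".join, axis=1)
        alphas = strata.copy()
        alphas["alpha"] = [const + float(np.asarray(re[k]).ravel()[0]) for k in keys]
        residual_sd = float(np.sqrt(res.scale))
        diagnostics = {
            "n_obs": len(df),
            "n_strata": len(strata),
            "converged": bool(res.converged),
            "re_var": float(np.asarray(res.cov_re).ravel()[0]),
        }
    logger.info(
        "forecast model (%s on %s): beta1=%.5f, residual sd=%.4f, %d strata",
        method, covariate_name, beta1, residual_sd, diagnostics["n_strata"],
    )
    return ForecastModel(
        beta1=beta1,
        alphas=alphas,
        covariate_name=covariate_name,
        residual_sd=residual_sd,
        method=method,
        diagnostics=diagnostics,
    )


def project(model: ForecastModel, covariate_forecast: pd.DataFrame) -> pd.DataFrame:
    """Predicted prevalence per stratum-year: expit(beta1 * x + alpha)."""
    df = covariate_forecast.rename(columns={"value": "x"}).copy()
    merged = df.merge(model.alphas, on=STRATUM_COLS, how="left")
    if merged["alpha"].isna().any():
        bad = merged.loc[merged["alpha"].isna(), STRATUM_COLS].drop_duplicates()
        raise ValueError(
            f"strata unseen at fit time: {bad.head(5).to_dict('records')}"
        )
    merged["value"] = _expit(model.beta1 * merged["x"].to_numpy()
                             + merged["alpha"].to_numpy())
    keep = [c for c in ("location", "age_start", "age_end", "sex", "year") if c in merged]
    return merged[keep + ["value"]]


def intercept_shift(projection: pd.DataFrame, estimate_anchor: pd.DataFrame,
                    anchor_year: int = 2021) -> pd.DataFrame:
    """Anchor the projection to the estimated prevalence at *anchor_year*.

    The per-stratum difference (estimate − projection) at the anchor year,
    in natural rate space, is added to every projected year; results are
    clamped to [0, 1] (clamp events counted and logged). The shifted
    series equals the estimate exactly at the anchor year.
    """
    proj_anchor = projection[projection["year"] == anchor_year]
    est = estimate_anchor[estimate_anchor["year"] == anchor_year] \
        if "year" in estimate_anchor.columns else estimate_anchor
    offs = proj_anchor.merge(
        est.rename(columns={"value": "estimate"})[STRATUM_COLS + ["estimate"]],
        on=STRATUM_COLS, how="left",
    )
    if offs["estimate"].isna().any() or len(offs) != len(proj_anchor):
        raise ValueError("estimate and projection grids misaligned at the anchor year")
    offs["offset"] = offs["estimate"] - offs["value"]
    out = projection.merge(offs[STRATUM_COLS + ["offset"]], on=STRATUM_COLS, how="left")
    if out["offset"].isna().any():
        raise ValueError("projection strata missing from the anchor-year grid")
    shifted = out["value"].to_numpy() + out["offset"].to_numpy()
    n_clamped = int(((shifted < 0) | (shifted > 1)).sum())
    if n_clamped:
        logger.warning("intercept shift clamped %d cell-years to [0, 1]", n_clamped)
    out["value"] = np.clip(shifted, 0.0, 1.0)
    out.attrs["n_clamped"] = n_clamped
    return out.drop(columns="offset")


def forecast_counts(prevalence_forecast: pd.DataFrame,
                    population_forecast: pd.DataFrame) -> pd.DataFrame:
    """Cases = prevalence × population per cell; totals aggregate by summation."""
    keys = [c for c in ("location", "age_start", "age_end", "sex", "year")
            if c in prevalence_forecast.columns and c in population_forecast.columns]
    merged = prevalence_forecast.merge(
        population_forecast.rename(columns={"value": "population"})[keys + ["population"]],
        on=keys, how="left",
    )
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), keys].drop_duplicates()
        raise ValueError(f"population missing for cells: {bad.head(5).to_dict('records')}")
    merged["cases"] = merged["value"] * merged["population"]
    return merged[keys + ["cases"]]
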