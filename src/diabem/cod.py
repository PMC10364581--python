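"""Redistribution of deaths coded to unspecified diabetes type.

In cause-of-death data, more than half of diabetes deaths typically carry
no type code. The redistribution model predicts, per demographic cell, the
type 2 share among type-coded deaths from age, sex and the population
obesity prevalence, using a log-linear regression trained only on
country-years with trustworthy type coding:

* filter 1 — more than 50% of the country-year's diabetes deaths carry a
  type code;
* filter 2 — at least 70% of type-specific deaths above age 25 are coded
  to type 2 (guards against registries that dump adult deaths on type 1).

Unspecified deaths are then split by the predicted proportion, all deaths
below age 15 are assigned to type 1, and per-cell totals are conserved
exactly. Deaths remain real-valued (no integer rounding) since downstream
years-of-life-lost are real-valued anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["TypeSplitModel", "select_training_rows", "fit_type_split",
           "redistribute_unspecified"]

logger = logging.getLogger(__name__)

_SHARE_CLIP = 1e-4
UNDER15_AGE = 15.0


def select_training_rows(deaths: pd.DataFrame, obesity: pd.DataFrame) -> pd.DataFrame:
    """Keep country-years whose type coding passes both inclusion filters.

    *deaths* has one row per (location, age_start, age_end, sex, year) with
    columns ``type1``, ``type2``, ``unspecified``. The returned frame is at
    country-year-age-sex resolution (only cells from passing country-years),
    with the country-year obesity prevalence merged in.
    """
    if "age_start" not in deaths.columns:
        raise ValueError("death table must carry age information (age_start)")
    cy = deaths.groupby(["location", "year"], as_index=False).agg(
        type1=("type1", "sum"), type2=("type2", "sum"),
        unspecified=("unspecified", "sum"),
    )
    # "older than 25": age groups starting at 25 or above
    over25 = (
        deaths[deaths["age_start"] >= 25.0]
        .groupby(["location", "year"], as_index=False)
        .agg(t1_o25=("type1", "sum"), t2_o25=("type2", "sum"))
    )
    cy = cy.merge(over25, on=["location", "year"], how="left").fillna(0.0)
    total = cy["type1"] + cy["type2"] + cy["unspecified"]
    coded = cy["type1"] + cy["type2"]
    with np.errstate(invalid="ignore", divide="ignore"):
        coded_frac = np.where(total > 0, coded / np.where(total > 0, total, 1.0), 0.0)
        o25_coded = cy["t1_o25"] + cy["t2_o25"]
        t2_frac_o25 = np.where(
            o25_coded > 0, cy["t2_o25"] / np.where(o25_coded > 0, o25_coded, 1.0), 0.0
        )
    pass1 = coded_frac > 0.5
    pass2 = t2_frac_o25 >= 0.7
    for row, p1, p2, cf, tf in zip(cy.itertuples(), pass1, pass2, coded_frac, t2_frac_o25):
        if not p1:
            logger.info(
                "excluding %s %s: only %.1f%% of diabetes deaths type-coded "
                "(filter: >50%% coded)", row.location, row.year, 100 * cf
            )
        elif not p2:
            logger.info(
                "excluding %s %s: only %.1f%% of over-25 type-specific deaths "
                "coded type 2 (filter: >=70%%)", row.location, row.year, 100 * tf
            )
    keep = cy.loc[pass1 & pass2, ["location", "year"]]
    out = deaths.merge(keep, on=["location", "year"])
    out = out.merge(
        obesity.rename(columns={"value": "obesity"}), on=["location", "year"],
        how="left",
    )
    if out["obesity"].isna().any():
        raise ValueError("obesity covariate missing for some training country-years")
    return out.reset_index(drop=True)


@dataclass
class TypeSplitModel:
    """Fitted regression for the type 2 share among type-coded deaths."""

    params: pd.Series
    cov: pd.DataFrame
    link: str  # "log" (default) or "logit"
    n_training_rows: int
    obesity_coefficient: float
    obesity_ci: tuple

    def predict_share(self, age_mid, sex_male, obesity) -> np.ndarray:
        """Predicted type 2 proportion, clamped to [0, 1]; 0 below age 15."""
        age_mid = np.asarray(age_mid, dtype=float)
        x = np.column_stack([
            np.ones_like(age_mid),
            age_mid,
            np.asarray(sex_male, dtype=float) * np.ones_like(age_mid),
            np.asarray(obesity, dtype=float) * np.ones_like(age_mid),
        ])
        eta = x @ self.params.to_numpy()
        if self.link == "log":
            share = np.exp(eta)
        else:
            share = 1.0 / (1.0 + np.exp(-eta))
        share = np.clip(share, 0.0, 1.0)
        return np.where(age_mid < UNDER15_AGE, 0.0, share)


def fit_type_split(training: pd.DataFrame, link: str = "log") -> TypeSplitModel:
    """Regress the observed type 2 share on age, sex and obesity prevalence.

    The default link follows the redistribution model's log-linear form
    (linear model of the log share); a logit variant is available. Rows are
    weighted by their coded death counts. Requires >= 10 rows spanning at
    least two obesity levels.
    """
    if link not in ("log", "logit"):
        raise ValueError("link must be 'log' or 'logit'")
    df = training.copy()
    coded = df["type1"] + df["type2"]
    df = df[coded > 0].copy()
    if len(df) < 10:
        raise ValueError("need at least 10 training rows with type-coded deaths")
    if df["obesity"].nunique() < 2:
        raise ValueError("training data must span at least two obesity levels")
    share = (df["type2"] / (df["type1"] + df["type2"])).clip(_SHARE_CLIP, 1 - _SHARE_CLIP)
    y = np.log(share) if link == "log" else np.log(share / (1 - share))
    age_mid = (df["age_start"] + df["age_end"]) / 2.0
    x = pd.DataFrame({
        "const": 1.0,
        "age_mid": age_mid,
        "sex_male": (df["sex"] == "male").astype(float),
        "obesity": df["obesity"],
    })
    cond = np.linalg.cond(x.to_numpy() / np.abs(x.to_numpy()).max(axis=0))
    if cond > 1e8:
        raise ValueError(
            f"design matrix is (near-)collinear: condition number {cond:.3g}"
        )
    weights = (df["type1"] + df["type2"]).to_numpy()
    res = sm.WLS(y.to_numpy(), x, weights=weights).fit()
    ci = res.conf_int().loc["obesity"]
    model = TypeSplitModel(
        params=res.params,
        cov=res.cov_params(),
        link=link,
        n_training_rows=len(df),
        obesity_coefficient=float(res.params["obesity"]),
        obesity_ci=(float(ci[0]), float(ci[1])),
    )
    logger.info(
        "type-split model: %d rows, obesity coefficient %.4f (95%% CI %.4f to %.4f)",
        model.n_training_rows, model.obesity_coefficient, *model.obesity_ci,
    )
    return model


def redistribute_unspecified(
    deaths: pd.DataFrame, model: TypeSplitModel, obesity: pd.DataFrame
) -> pd.DataFrame:
    """Assign every death to type 1 or type 2.

    Unspecified deaths are split by the model's predicted type 2 share for
    the cell; below age 15 all deaths (coded or not) become type 1. The
    type1+type2 total equals the original all-type total in every cell.
    """
    df = deaths.merge(
        obesity.rename(columns={"value": "obesity"}), on=["location", "year"],
        how="left",
    )
    if df["obesity"].isna().any():
        raise ValueError("obesity covariate missing for some cells")
    age_mid = ((df["age_start"] + df["age_end"]) / 2.0).to_numpy()
    share = model.predict_share(
        age_mid, (df["sex"] == "male").to_numpy(dtype=float), df["obesity"].to_numpy()
    )
    t1 = df["type1"].to_numpy() + df["unspecified"].to_numpy() * (1.0 - share)
    t2 = df["type2"].to_numpy() + df["unspecified"].to_numpy() * share
    young = df["age_start"].to_numpy() < UNDER15_AGE
    t1 = np.where(young, t1 + t2, t1)
    t2 = np.where(young, 0.0, t2)
    out = deaths[["location", "age_start", "age_end", "sex", "year"]].copy()
    out["type1"] = t1
    out["type2"] = t2
    out["total"] = t1 + t2
    return out
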