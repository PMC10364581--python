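"""YLL / YLD / DALY accounting and age-standardisation.

Years of life lost (YLLs) are deaths × standard remaining life expectancy
at the age of death; years lived with disability (YLDs) are the prevalence
of each sequela × its disability weight, corrected for comorbidity with
background ill health assuming independent health states combined
multiplicatively; DALYs are the sum. All operations are draw-wise.

Age-standardised rates use a standard population built as the unweighted
mean of the age-proportional distributions of all locations whose total
population exceeds five million at the reference year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DrawSet, check_aligned

__all__ = [
    "StandardPopulation",
    "Sequela",
    "compute_yll",
    "compute_yld",
    "compute_daly",
    "build_standard_population",
    "age_standardise",
    "rate_per_100k",
    "representative_age",
]

POPULATION_THRESHOLD = 5_000_000


@dataclass(frozen=True)
class Sequela:
    """One modelled consequence of diabetes."""

    name: str
    disability_weight: float  # (0, 1)
    proportion: float  # share of prevalent cases in this state

    def __post_init__(self):
        if not 0.0 < self.disability_weight < 1.0:
            raise ValueError(
                f"disability weight for {self.name!r} must lie in (0, 1)"
            )
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"sequela proportion for {self.name!r} must be in [0, 1]")


@dataclass
class StandardPopulation:
    """Per-age-group weights summing to one."""

    age_starts: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.age_starts = np.asarray(self.age_starts, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("standard-population weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("standard-population weights must sum to 1")

    def weight_of(self) -> dict:
        return dict(zip(self.age_starts, self.weights))


def representative_age(age_start, age_end) -> np.ndarray:
    """Midpoint of the age group; the open-ended top group uses start + 2.5."""
    age_start = np.asarray(age_start, dtype=float)
    age_end = np.asarray(age_end, dtype=float)
    mid = (age_start + age_end) / 2.0
    return np.where(np.isinf(age_end), age_start + 2.5, mid)


def compute_yll(deaths: DrawSet, life_table) -> DrawSet:
    """YLL = deaths × remaining life expectancy at the representative age."""
    idx = deaths.index
    rep = representative_age(idx["age_start"], idx["age_end"])
    try:
        ex = life_table.remaining(rep)
    except ValueError as err:
        raise ValueError(f"age group missing from life table: {err}") from None
    return DrawSet(idx, deaths.draws * np.asarray(ex)[:, None])


def comorbidity_share(dw: float, background_dw: float) -> float:
    """Cause-specific share of the combined disability of two independent states.

    Independent states combine multiplicatively: combined = 1 − (1−dw)(1−b).
    The combined disability is allocated to each component proportionally
    to its own weight, so the cause keeps combined × dw / (dw + b). With no
    background disability the share is dw itself; with any background it is
    strictly smaller (the correction never increases YLDs).
    """
    if background_dw < 0:
        raise ValueError("background disability must be non-negative")
    if background_dw == 0:
        return dw
    combined = 1.0 - (1.0 - dw) * (1.0 - background_dw)
    return combined * dw / (dw + background_dw)


def compute_yld(
    prevalence: DrawSet,
    sequelae,
    population: pd.DataFrame,
    background_ylds_per_capita: float = 0.0,
) -> DrawSet:
    """Sequela-based YLDs with multiplicative comorbidity correction.

    ``prevalence`` is the cause prevalence (proportion) per cell;
    ``sequelae`` a list of :class:`Sequela` whose proportions partition the
    prevalent cases (mutually exclusive states); ``population`` a
    demographic table aligned with the prevalence grid;
    ``background_ylds_per_capita`` the average disability weight of
    co-occurring ill health in the population.
    """
    check_aligned(prevalence.index, population[[c for c in prevalence.index.columns]],
                  context="compute_yld")
    pop = population["value"].to_numpy()[:, None]
    total = np.zeros_like(prevalence.draws)
    for seq in sequelae:
        eff_dw = comorbidity_share(seq.disability_weight, background_ylds_per_capita)
        total += prevalence.draws * seq.proportion * eff_dw * pop
    return DrawSet(prevalence.index, total)


def compute_daly(yll: DrawSet, yld: DrawSet) -> DrawSet:
    """DALYs are the sum of YLLs and YLDs, draw-wise on aligned grids."""
    check_aligned(yll.index, yld.index, context="compute_daly")
    if yll.n_draws != yld.n_draws:
        raise ValueError("draw counts differ between YLLs and YLDs")
    return DrawSet(yll.index, yll.draws + yld.draws)


def build_standard_population(
    populations: pd.DataFrame, threshold: float = POPULATION_THRESHOLD
) -> StandardPopulation:
    """Unweighted mean of age distributions of locations above *threshold*.

    *populations* holds one reference-year population per (location,
    age_start) — sexes already summed. The threshold is strict: a location
    at exactly the threshold is excluded.
    """
    totals = populations.groupby("location")["value"].sum()
    qualifying = totals[totals > threshold].index
    if len(qualifying) == 0:
        raise ValueError(
            f"no location exceeds the {threshold:,.0f}-person threshold"
        )
    sub = populations[populations["location"].isin(qualifying)]
    pivot = sub.pivot_table(index="location", columns="age_start", values="value",
                            aggfunc="sum")
    dist = pivot.div(pivot.sum(axis=1), axis=0)
    weights = dist.mean(axis=0)
    return StandardPopulation(
        age_starts=weights.index.to_numpy(dtype=float),
        weights=weights.to_numpy(),
    )


def age_standardise(rates: DrawSet, std: StandardPopulation) -> DrawSet:
    """Weight age-specific rates by the standard population, draw-wise.

    ``rates`` must carry an ``age_start`` key column covering every
    standard age group; remaining key columns define the output cells.
    """
    idx = rates.index
    have = set(idx["age_start"].unique())
    missing = [a for a in std.age_starts if a not in have]
    if missing:
        raise ValueError(f"rates missing standard age groups: {missing}")
    wmap = std.weight_of()
    w = idx["age_start"].map(wmap)
    if w.isna().any():
        extra = sorted(set(idx.loc[w.isna(), "age_start"]))
        raise ValueError(f"rates carry age groups outside the standard: {extra}")
    weighted = DrawSet(idx, rates.draws * w.to_numpy()[:, None])
    return weighted.aggregate(over=["age_start", "age_end"])


def rate_per_100k(count: DrawSet, population: pd.DataFrame) -> DrawSet:
    """Events per 100 000 population, draw-wise."""
    check_aligned(count.index, population[[c for c in count.index.columns]],
                  context="rate_per_100k")
    pop = population["value"].to_numpy()
    zero_pop = pop <= 0
    if np.any(zero_pop & (np.abs(count.draws).max(axis=1) > 0)):
        raise ValueError("zero population in cells with non-zero counts")
    safe = np.where(zero_pop, 1.0, pop)
    rates = np.where(zero_pop[:, None], 0.0, count.draws / safe[:, None] * 1e5)
    return DrawSet(count.index, rates)
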