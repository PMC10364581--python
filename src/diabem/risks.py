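"""Comparative risk assessment: relative-risk curves, TMRELs, and PAFs.

A risk factor is described by an exposure distribution (categorical
probabilities or a continuous density on an exposure grid), a relative-risk
curve (piecewise-linear between grid points), and a theoretical minimum
risk exposure level (TMREL) — the counterfactual exposure minimising
diabetes risk. The population attributable fraction (PAF) is the
proportional reduction in burden that would occur if the whole population
were moved to the TMREL::

    PAF = (E[RR(X)] - 1) / E[RR(X)]        with RR normalised so RR(TMREL)=1

Attributable DALYs are PAF × DALYs, draw-wise. Overlapping risks are
combined multiplicatively under an independence approximation (no
mediation adjustment): 1 - prod_j (1 - PAF_j).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import DrawSet, check_aligned
from .reporting import summarise

__all__ = [
    "RelativeRiskCurve",
    "ExposureDistribution",
    "RiskFactor",
    "normalize_rr",
    "compute_paf",
    "attributable_burden",
    "aggregate_pafs",
    "paf_percentage_change",
]

_NORMALISATION_TOL = 1e-9


@dataclass
class RelativeRiskCurve:
    """Relative risk as a piecewise-linear function of continuous exposure."""

    grid: np.ndarray
    rr: np.ndarray
    units: str = ""
    normalised_at: object = None  # TMREL once normalised

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.rr.shape:
            raise ValueError("grid and rr must be 1-d arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("exposure grid must be strictly increasing")
        if np.any(self.rr <= 0):
            raise ValueError("relative risks must be strictly positive")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.grid[0]) or np.any(x > self.grid[-1]):
            raise ValueError("exposure outside the curve's grid")
        return np.interp(x, self.grid, self.rr)


@dataclass
class ExposureDistribution:
    """Either categorical probabilities or a continuous density on a grid."""

    grid: np.ndarray | None = None
    density: np.ndarray | None = None
    categories: dict | None = None

    def __post_init__(self):
        if (self.categories is None) == (self.density is None):
            raise ValueError("provide either categories or (grid, density)")
        if self.categories is not None:
            probs = np.array(list(self.categories.values()), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
                raise ValueError("category probabilities must be >= 0 and sum to 1")
        else:
            self.grid = np.asarray(self.grid, dtype=float)
            self.density = np.asarray(self.density, dtype=float)
            if self.grid.shape != self.density.shape:
                raise ValueError("grid and density must have equal length")
            if np.any(self.density < 0):
                raise ValueError("density must be non-negative")
            mass = np.trapezoid(self.density, self.grid)
            if abs(mass - 1.0) > 1e-6:
                raise ValueError(f"density must integrate to 1 (got {mass:.6f})")

    @property
    def is_categorical(self) -> bool:
        return self.categories is not None

    @classmethod
    def normal(cls, mean: float, sd: float, grid: np.ndarray) -> "ExposureDistribution":
        """Truncated-normal density on *grid*, renormalised to unit mass."""
        grid = np.asarray(grid, dtype=float)
        dens = np.exp(-((grid - mean) ** 2) / (2 * sd**2))
        dens = dens / np.trapezoid(dens, grid)
        return cls(grid=grid, density=dens)


@dataclass
class RiskFactor:
    """Registry entry: curve + TMREL + exposure + which diabetes types it affects."""

    name: str
    curve: RelativeRiskCurve | None
    tmrel: object  # float, (lo, hi) interval, or a category label
    applies_to: tuple = ("type2",)
    exposure: ExposureDistribution | None = None
    categorical_rr: dict | None = None


def normalize_rr(curve: RelativeRiskCurve, tmrel) -> RelativeRiskCurve:
    """Divide the curve by its value at the TMREL (mean value over an interval).

    After normalisation RR(TMREL) = 1, the reference point for the PAF.
    """
    if isinstance(tmrel, (tuple, list)):
        lo, hi = float(tmrel[0]), float(tmrel[1])
        if lo > hi:
            raise ValueError("TMREL interval must satisfy lo <= hi")
        if lo < curve.grid[0] or hi > curve.grid[-1]:
            raise ValueError("TMREL interval outside the exposure grid")
        if lo == hi:
            ref = float(curve(lo))
        else:
            xs = np.union1d(np.linspace(lo, hi, 101), curve.grid[(curve.grid >= lo) & (curve.grid <= hi)])
            ref = float(np.trapezoid(curve(xs), xs) / (hi - lo))
    else:
        t = float(tmrel)
        if t < curve.grid[0] or t > curve.grid[-1]:
            raise ValueError("TMREL outside the exposure grid")
        ref = float(curve(t))
    return replace(curve, rr=curve.rr / ref, normalised_at=tmrel)


def _tmrel_value(curve: RelativeRiskCurve):
    t = curve.normalised_at
    if t is None:
        raise ValueError("curve has not been normalised at a TMREL")
    if isinstance(t, (tuple, list)):
        lo, hi = float(t[0]), float(t[1])
        if lo == hi:
            return float(curve(lo))
        xs = np.union1d(np.linspace(lo, hi, 101), curve.grid[(curve.grid >= lo) & (curve.grid <= hi)])
        return float(np.trapezoid(curve(xs), xs) / (hi - lo))
    return float(curve(float(t)))


def compute_paf(exposure: ExposureDistribution, curve=None, categorical_rr=None,
                tmrel_category=None) -> float:
    """Population attributable fraction for one risk factor.

    Continuous: ``PAF = (∫ p(x) RR(x) dx − 1)/∫ p(x) RR(x) dx`` with
    trapezoid integration on the exposure grid; the curve must already be
    normalised (``RR(TMREL)=1`` within 1e-9). Categorical: the analogous
    probability-weighted sum, with the TMREL category's RR as reference.
    Negative PAFs are possible when observed exposure is protective
    relative to the TMREL.
    """
    if exposure.is_categorical:
        if categorical_rr is None:
            raise ValueError("categorical exposure requires categorical_rr")
        ref_label = tmrel_category
        if ref_label is None:
            ref_label = min(categorical_rr, key=categorical_rr.get)
        ref = categorical_rr[ref_label]
        if abs(ref - min(categorical_rr.values())) > _NORMALISATION_TOL:
            raise ValueError("TMREL category must carry the minimum relative risk")
        mean_rr = sum(
            p * categorical_rr[label] / ref for label, p in exposure.categories.items()
        )
    else:
        if curve is None:
            raise ValueError("continuous exposure requires a relative-risk curve")
        check = _tmrel_value(curve)
        if abs(check - 1.0) > _NORMALISATION_TOL:
            raise ValueError(
                f"curve is not normalised at its TMREL (RR(TMREL)={check:.6g}); "
                "call normalize_rr first"
            )
        rr_on_grid = curve(exposure.grid)
        mean_rr = float(np.trapezoid(exposure.density * rr_on_grid, exposure.grid))
        mass = float(np.trapezoid(exposure.density, exposure.grid))
        mean_rr /= mass  # guard against grid-truncation mass loss
    return (mean_rr - 1.0) / mean_rr


def paf_for_risk(risk: RiskFactor, exposure: ExposureDistribution | None = None) -> float:
    """Convenience wrapper resolving a registry entry into a PAF."""
    exp_dist = exposure if exposure is not None else risk.exposure
    if exp_dist is None:
        raise ValueError(f"risk {risk.name!r} has no exposure distribution")
    if exp_dist.is_categorical:
        return compute_paf(exp_dist, categorical_rr=risk.categorical_rr,
                           tmrel_category=risk.tmrel if isinstance(risk.tmrel, str) else None)
    curve = risk.curve
    if curve.normalised_at is None:
        curve = normalize_rr(curve, risk.tmrel)
    return compute_paf(exp_dist, curve=curve)


def attributable_burden(paf: DrawSet, dalys: DrawSet) -> DrawSet:
    """Attributable DALYs = PAF × DALYs, draw-wise on aligned grids."""
    check_aligned(paf.index, dalys.index, context="attributable_burden")
    if paf.n_draws != dalys.n_draws:
        raise ValueError("draw counts differ between PAFs and DALYs")
    return DrawSet(dalys.index, paf.draws * dalys.draws)


def aggregate_pafs(pafs: list) -> DrawSet:
    """Combine PAFs for distinct risks: 1 − Π(1 − PAF_j), draw-wise.

    This is the independence approximation; overlapping causal pathways
    (mediation) are deliberately not modelled, and the result is an upper
    bound on the jointly attributable fraction only in that sense.
    """
    if not pafs:
        raise ValueError("need at least one PAF")
    first = pafs[0]
    prod = np.ones_like(first.draws)
    for p in pafs:
        check_aligned(first.index, p.index, context="aggregate_pafs")
        if np.any(p.draws >= 1.0):
            raise ValueError("PAF draws must be < 1")
        prod *= 1.0 - p.draws
    return DrawSet(first.index, 1.0 - prod)


def paf_percentage_change(paf_t0: DrawSet, paf_t1: DrawSet):
    """Draw-wise percent change in PAF between two periods, summarised.

    Computed per draw and only then summarised — summary-level arithmetic
    on rounded PAFs gives a different (and not reported) number.
    """
    check_aligned(paf_t0.index, paf_t1.index, context="paf_percentage_change")
    if np.any(paf_t0.draws <= 0):
        raise ValueError("baseline PAF draws must be strictly positive")
    change = (paf_t1.draws - paf_t0.draws) / paf_t0.draws * 100.0
    return DrawSet(paf_t0.index, change), summarise(change.ravel())
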