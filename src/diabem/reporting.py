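"""Draw-based uncertainty propagation and presentation conventions.

Uncertainty is carried as 100 Monte-Carlo draws per demographic cell
(configurable); 95% uncertainty intervals are the 2.5th and 97.5th
percentiles across draws, computed with linear interpolation between order
statistics.  Counts are printed to three significant figures; rates and
percentages to one decimal place, rounding half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .containers import DrawSet

DEFAULT_N_DRAWS = 100


@dataclass(frozen=True)
class SummarisedEstimate:
    """Mean and 95% uncertainty interval of a draw vector."""

    mean: float
    lower: float
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower percentile exceeds upper percentile")

    def formatted(self, kind: str = "rate") -> str:
        return (
            f"{format_value(self.mean, kind)} "
            f"({format_value(self.lower, kind)}–{format_value(self.upper, kind)})"
        )


def make_draws(
    mean,
    uncertainty,
    n: int = DEFAULT_N_DRAWS,
    seed: int | None = None,
    family: str = "normal",
):
    """Sample *n* draws per element around *mean*.

    ``family`` selects the declared distribution: ``"normal"`` (natural
    space), ``"lognormal"`` (normal in log space, for non-negative rates and
    counts) or ``"logit-normal"`` (normal in logit space, for proportions).
    ``uncertainty`` is the standard deviation in the transformed space.
    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 draws")
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    sd = np.broadcast_to(np.asarray(uncertainty, dtype=float), mean.shape)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((mean.size, n))
    sd_col = sd.reshape(-1, 1)
    if family == "normal":
        draws = mean.reshape(-1, 1) + sd_col * eps
    elif family == "lognormal":
        base = np.log(np.maximum(mean.reshape(-1, 1), 1e-300))
        draws = np.exp(base + sd_col * eps)
    elif family == "logit-normal":
        clamped = np.clip(mean.reshape(-1, 1), 1e-9, 1 - 1e-9)
        base = np.log(clamped / (1 - clamped))
        draws = 1.0 / (1.0 + np.exp(-(base + sd_col * eps)))
    else:
        raise ValueError(f"unknown draw family: {family!r}")
    return draws.reshape(mean.shape + (n,))


def summarise(draws) -> SummarisedEstimate:
    """Mean plus 2.5th/97.5th percentile summary of a draw vector.

    Accepts a 1-d array of draws. Quantiles use linear interpolation
    between order statistics (the numpy default), which is the declared
    rule throughout the package.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 2:
        raise ValueError("need at least 2 draws to summarise")
    lower, upper = np.percentile(draws, [2.5, 97.5])
    return SummarisedEstimate(mean=float(draws.mean()), lower=float(lower), upper=float(upper))


def summarise_drawset(ds: DrawSet):
    """Per-cell summary of a DrawSet as a tidy frame."""
    out = ds.index.copy()
    out["mean"] = ds.draws.mean(axis=1)
    out["lower"] = np.percentile(ds.draws, 2.5, axis=1)
    out["upper"] = np.percentile(ds.draws, 97.5, axis=1)
    return out


def _round_half_away(value: float, decimals: int) -> float:
    """Round half away from zero at the given number of decimals."""
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def format_value(value: float, kind: str) -> str:
    """Render a number under the reporting conventions.

    ``count`` → three significant figures (space-grouped thousands);
    ``rate`` and ``percent`` → one decimal place. Half-way cases round
    away from zero.
    """
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"cannot format non-finite value {value!r}")
    if kind in ("rate", "percent"):
        return f"{_round_half_away(value, 1):.1f}"
    if kind != "count":
        raise ValueError(f"unknown format kind {kind!r}")
    if value == 0:
        return "0"
    magnitude = math.floor(math.log10(abs(value)))
    decimals = 2 - magnitude
    rounded = _round_half_away(value, decimals)
    if decimals <= 0:
        text = f"{rounded:,.0f}".replace(",", " ")
    else:
        text = f"{rounded:.{decimals}f}"
    return text


def percent_of(numerator: float, denominator: float) -> float:
    """Share of *denominator* made up by *numerator*, in percent, 1 decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return _round_half_away(numerator / denominator * 100.0, 1)


def percentage_change(v0, v1) -> SummarisedEstimate:
    """Draw-wise percentage change from *v0* to *v1*, then summarised.

    The change is computed per draw — never from rounded summary values —
    so skewed draw distributions are handled correctly.
    """
    v0 = np.asarray(v0, dtype=float).ravel()
    v1 = np.asarray(v1, dtype=float).ravel()
    if v0.shape != v1.shape:
        raise ValueError("draw vectors must have the same length")
    if np.any(v0 <= 0):
        raise ValueError("baseline draws must be strictly positive")
    return summarise((v1 - v0) / v0 * 100.0)
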