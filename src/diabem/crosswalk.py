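"""Case-definition crosswalks with least-trimmed-squares robustness.

Prevalence datapoints measured under alternate case definitions (HbA1c,
OGTT, post-prandial glucose, ...) are adjusted onto the reference
definition (fasting plasma glucose >= 7 mmol/L or medication use) by a
log-ratio estimated from matched reference/alternate pairs. The estimator
is least-trimmed squares (LTS): exactly ceil(trim_fraction * n) pairs —
10% by default — are excluded, chosen to minimise the trimmed sum of
squared residuals, which makes the fit immune to gross outliers up to the
trim fraction.

For the intercept-only (single log-ratio) model solved here, the optimal
LTS subset of h points is always a contiguous window of the sorted
residuals, so the exact optimum is found by a sorted sliding-window scan
at any n — no combinatorial search or concentration heuristic is needed.

Population mean fasting plasma glucose reports are converted to prevalence
as the upper-tail mass above the 7 mmol/L threshold under a configured
two-parameter distribution (lognormal by default, normal optional).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DefinitionRatio",
    "estimate_definition_ratios",
    "adjust_datapoints",
    "mean_fpg_to_prevalence",
    "REFERENCE_DEFINITION",
    "FPG_THRESHOLD_MMOL_L",
]

REFERENCE_DEFINITION = "fpg_ref"
FPG_THRESHOLD_MMOL_L = 7.0
DEFAULT_TRIM = 0.10


@dataclass
class DefinitionRatio:
    """Estimated log-ratio of one case definition relative to the reference."""

    definition: str
    log_ratio: float
    se: float
    n_pairs: int
    trim_mask: np.ndarray  # True where the pair was trimmed

    def to_dict(self) -> dict:
        return {
            "definition": self.definition,
            "log_ratio": self.log_ratio,
            "se": self.se,
            "n_pairs": self.n_pairs,
            "trimmed_indices": np.flatnonzero(self.trim_mask).tolist(),
        }


def _lts_location(values: np.ndarray, trim_fraction: float):
    """Exact LTS location estimate of 1-d *values*.

    Returns (estimate, se, keep_mask). The optimal h-subset minimising the
    SS around its own mean is a contiguous window in sorted order; all
    n - h + 1 windows are scanned.
    """
    n = values.size
    n_trim = int(np.ceil(trim_fraction * n))
    h = n - n_trim
    order = np.argsort(values, kind="stable")
    v = values[order]
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csq = np.concatenate([[0.0], np.cumsum(v * v)])
    starts = np.arange(n - h + 1)
    win_sum = csum[starts + h] - csum[starts]
    win_sq = csq[starts + h] - csq[starts]
    ss = win_sq - win_sum**2 / h
    best = int(np.argmin(ss))
    keep_sorted = np.zeros(n, dtype=bool)
    keep_sorted[best : best + h] = True
    keep = np.zeros(n, dtype=bool)
    keep[order] = keep_sorted
    estimate = win_sum[best] / h
    if h > 1:
        se = float(np.sqrt(max(ss[best], 0.0) / (h - 1)) / np.sqrt(h))
    else:
        se = 0.0
    return float(estimate), se, keep


def estimate_definition_ratios(
    pairs: pd.DataFrame, trim_fraction: float = DEFAULT_TRIM
) -> dict:
    """Estimate the log-ratio to the reference per alternate definition.

    *pairs* has columns ``definition``, ``ref_value``, ``alt_value`` — one
    row per matched observation of the same stratum under both definitions.
    Requires >= 5 pairs per definition and ``0 <= trim_fraction < 0.5``.
    Returns a dict mapping definition → :class:`DefinitionRatio`, always
    including the reference itself with log-ratio exactly 0 and SE 0.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    out = {
        REFERENCE_DEFINITION: DefinitionRatio(
            REFERENCE_DEFINITION, 0.0, 0.0, 0, np.zeros(0, dtype=bool)
        )
    }
    for definition, block in pairs.groupby("definition"):
        if definition == REFERENCE_DEFINITION:
            continue
        ref = block["ref_value"].to_numpy(dtype=float)
        alt = block["alt_value"].to_numpy(dtype=float)
        if len(block) < 5:
            raise ValueError(
                f"definition {definition!r}: need >= 5 matched pairs, got {len(block)}"
            )
        if np.any(ref <= 0) or np.any(alt <= 0):
            raise ValueError(f"definition {definition!r}: pair values must be positive")
        log_ratios = np.log(alt / ref)
        est, se, keep = _lts_location(log_ratios, trim_fraction)
        out[definition] = DefinitionRatio(
            definition=str(definition),
            log_ratio=est,
            se=se,
            n_pairs=len(block),
            trim_mask=~keep,
        )
    return out


def adjust_datapoints(datapoints: pd.DataFrame, ratios: dict) -> pd.DataFrame:
    """Map datapoints onto the reference definition scale.

    Adjusted value = observed × exp(−log_ratio); the ratio's own
    uncertainty is propagated into the standard error by the delta method
    (added in quadrature on the adjusted scale), so adjusted SEs are never
    smaller than the original sampling SEs. Reference-definition rows pass
    through unchanged.
    """
    missing = set(datapoints["definition"]) - set(ratios)
    if missing:
        raise ValueError(f"no crosswalk ratio for definitions: {sorted(missing)}")
    out = datapoints.copy()
    log_r = out["definition"].map(lambda d: ratios[d].log_ratio).to_numpy()
    se_r = out["definition"].map(lambda d: ratios[d].se).to_numpy()
    adjusted = out["value"].to_numpy() * np.exp(-log_r)
    out["value"] = adjusted
    out["se"] = np.sqrt(out["se"].to_numpy() ** 2 + (adjusted * se_r) ** 2)
    return out


def mean_fpg_to_prevalence(
    mean_fpg: float,
    spread: float,
    threshold: float = FPG_THRESHOLD_MMOL_L,
    family: str = "lognormal",
) -> float:
    """Diabetes prevalence implied by a population mean FPG report.

    Returns the upper-tail probability P(FPG >= threshold) under a
    two-parameter population distribution of fasting plasma glucose with
    the given mean and standard deviation (both mmol/L). ``lognormal``
    (default) matches the right skew of glucose distributions; ``normal``
    is available for sensitivity analysis.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    if mean_fpg <= 0:
        raise ValueError("mean FPG must be positive")
    if family == "normal":
        return float(stats.norm.sf(threshold, loc=mean_fpg, scale=spread))
    if family == "lognormal":
        sigma2 = np.log1p((spread / mean_fpg) ** 2)
        mu = np.log(mean_fpg) - sigma2 / 2.0
        return float(stats.lognorm.sf(threshold, s=np.sqrt(sigma2), scale=np.exp(mu)))
    raise ValueError("family must be 'lognormal' or 'normal'")


def ratios_to_json(ratios: dict) -> list:
    """Serialisable audit record of the estimated ratios and trim masks."""
    return [r.to_dict() for r in ratios.values()]
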