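"""Illness-death consistency modelling.

The compartmental model tracks a birth cohort along age ``a`` at a fixed
calendar year (period approximation) with a susceptible fraction ``S(a)``
and a case fraction ``C(a)``::

    dS/da = -(i + m) S + r C
    dC/da =  i S - (r + m + f) C

where ``i`` is incidence, ``r`` remission, ``f`` excess (case-specific)
mortality and ``m`` background mortality, all per person-year and
piecewise-constant within age groups. Prevalence is ``p = C / (S + C)``
and the cause-specific mortality rate is ``csmr = p * f``, so the five
measures returned are mutually consistent by construction.

Rates are fitted to noisy prevalence datapoints and a CSMR series with a
penalised weighted least-squares objective on log-rate spline knots, with
box constraints (annual remission capped, 1%/year by default for total
diabetes; zero remission for type 1). Fit uncertainty comes from a
nonparametric bootstrap of the datapoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .containers import DrawSet, check_aligned

__all__ = [
    "RateBundle",
    "CompartmentState",
    "solve_illness_death",
    "fit_rates",
    "FitResult",
    "subtract_type1",
    "assign_under15_to_type1",
]

REMISSION_CAP_DEFAULT = 0.01  # per year, total diabetes
_LOG_RATE_FLOOR = np.log(1e-8)
_LOG_RATE_CEIL = np.log(10.0)


class DomainError(ValueError):
    """Raised for rate inputs outside the model's domain."""


@dataclass
class RateBundle:
    """The five consistent epidemiological measures on one age grid."""

    age_edges: np.ndarray  # length n_groups + 1, strictly increasing
    incidence: np.ndarray
    remission: np.ndarray
    excess_mortality: np.ndarray
    background_mortality: np.ndarray
    prevalence: np.ndarray | None = None
    csmr: np.ndarray | None = None

    def __post_init__(self):
        self.age_edges = np.asarray(self.age_edges, dtype=float)
        n = len(self.age_edges) - 1
        if n < 1 or np.any(np.diff(self.age_edges) <= 0):
            raise DomainError("age edges must be strictly increasing with >= 2 entries")
        for name in ("incidence", "remission", "excess_mortality", "background_mortality"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape[-1] != n:
                raise DomainError(f"{name} must have one value per age group ({n})")
            if np.any(arr < 0):
                raise DomainError(f"{name} must be non-negative")
            setattr(self, name, arr)

    @property
    def n_groups(self) -> int:
        return len(self.age_edges) - 1

    @property
    def age_starts(self) -> np.ndarray:
        return self.age_edges[:-1]

    def consistency_residual(self) -> float:
        """max |csmr - p*f|; ~0 on any solver output."""
        if self.prevalence is None or self.csmr is None:
            raise ValueError("bundle has not been solved yet")
        return float(np.max(np.abs(self.csmr - self.prevalence * self.excess_mortality)))


@dataclass
class CompartmentState:
    """Susceptible/case fractions of the birth cohort at the age-group starts."""

    susceptible: np.ndarray
    cases: np.ndarray


def _expm2_apply(a11, a12, a21, a22, t, s, c):
    """Apply exp(t*A) to the state (s, c) for the 2x2 system A=[[a11,a12],[a21,a22]].

    Vectorised over leading dimensions. Eigenvalues are always real here
    because the off-diagonal entries (incidence, remission) are non-negative.
    """
    mu = 0.5 * (a11 + a22) * t
    half_diff = 0.5 * (a11 - a22) * t
    disc = half_diff**2 + (a12 * t) * (a21 * t)
    delta = np.sqrt(np.maximum(disc, 0.0))
    cosh_d = np.cosh(delta)
    small = delta < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        sinhc = np.where(small, 1.0 + delta**2 / 6.0, np.sinh(delta) / np.where(small, 1.0, delta))
    scale = np.exp(mu)
    # exp(tA) = e^mu [cosh(d) I + sinhc(d) (tA - mu I)]
    m11 = scale * (cosh_d + sinhc * (a11 * t - mu))
    m12 = scale * sinhc * a12 * t
    m21 = scale * sinhc * a21 * t
    m22 = scale * (cosh_d + sinhc * (a22 * t - mu))
    return m11 * s + m12 * c, m21 * s + m22 * c


def solve_illness_death(
    incidence,
    remission,
    excess_mortality,
    background_mortality,
    age_edges,
    p0: float = 0.0,
) -> RateBundle:
    """Integrate the illness-death equations and return a consistent bundle.

    Rates are piecewise-constant within age groups; each group's prevalence
    is evaluated at the group's start age (the solution within the group is
    the exact matrix exponential of the constant-coefficient system, so the
    solver error is at machine precision rather than discretisation order).

    Supports batched rate arrays with shape ``(..., n_groups)``; the
    returned bundle then carries batched prevalence/csmr arrays.
    """
    bundle = RateBundle(
        age_edges=age_edges,
        incidence=incidence,
        remission=remission,
        excess_mortality=excess_mortality,
        background_mortality=background_mortality,
    )
    if not 0.0 <= p0 <= 1.0:
        raise DomainError("p0 must be a proportion in [0, 1]")
    i, r, f, m = (
        bundle.incidence,
        bundle.remission,
        bundle.excess_mortality,
        bundle.background_mortality,
    )
    i, r, f, m = np.broadcast_arrays(i, r, f, m)
    widths = np.diff(bundle.age_edges)
    lead = i.shape[:-1]
    s = np.full(lead, 1.0 - p0)
    c = np.full(lead, float(p0))
    n = bundle.n_groups
    prevalence = np.empty(i.shape)
    S_path = np.empty(i.shape)
    C_path = np.empty(i.shape)
    underflow = False
    for k in range(n):
        tot = s + c
        zero = tot <= 0.0
        if np.any(zero):
            underflow = True
        with np.errstate(invalid="ignore", divide="ignore"):
            prevalence[..., k] = np.where(zero, 0.0, c / np.where(zero, 1.0, tot))
        S_path[..., k] = s
        C_path[..., k] = c
        ik, rk, fk, mk = i[..., k], r[..., k], f[..., k], m[..., k]
        s, c = _expm2_apply(
            -(ik + mk), rk, ik, -(rk + mk + fk), widths[k], s, c
        )
        s = np.maximum(s, 0.0)
        c = np.maximum(c, 0.0)
    if underflow:
        warnings.warn(
            "cohort fraction underflowed to zero; prevalence defined as 0 there",
            RuntimeWarning,
            stacklevel=2,
        )
    bundle.prevalence = prevalence
    bundle.csmr = prevalence * f
    bundle.state = CompartmentState(susceptible=S_path, cases=C_path)
    return bundle


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Point estimate plus bootstrap draws from :func:`fit_rates`."""

    bundle: RateBundle
    prevalence_draws: np.ndarray | None  # (n_draws, n_groups)
    incidence_draws: np.ndarray | None
    objective: float
    n_iterations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


def _knot_indices(n_groups: int, spacing: int = 2) -> np.ndarray:
    """Knot placement: one knot per *spacing* age groups, last group included."""
    idx = list(range(0, n_groups, spacing))
    if idx[-1] != n_groups - 1:
        idx.append(n_groups - 1)
    return np.asarray(idx)


def _interp_log(knot_idx, knot_vals, n_groups):
    """Linear interpolation of log-rates from knots to all age groups.

    knot_vals may be batched with shape (..., n_knots).
    """
    groups = np.arange(n_groups, dtype=float)
    if knot_vals.ndim == 1:
        return np.interp(groups, knot_idx, knot_vals)
    flat = knot_vals.reshape(-1, knot_vals.shape[-1])
    out = np.empty((flat.shape[0], n_groups))
    for j in range(flat.shape[0]):
        out[j] = np.interp(groups, knot_idx, flat[j])
    return out.reshape(knot_vals.shape[:-1] + (n_groups,))


def fit_rates(
    prevalence_data: pd.DataFrame,
    csmr,
    age_edges,
    background_mortality,
    *,
    remission_cap: float = REMISSION_CAP_DEFAULT,
    no_remission: bool = False,
    smoothness: float = 1e-1,
    csmr_rel_se: float = 0.05,
    n_draws: int = 0,
    seed: int | None = None,
    knot_spacing: int = 2,
    maxiter: int = 200,
    profile_remission: bool = True,
) -> FitResult:
    """Fit incidence, remission and excess mortality to noisy data.

    Parameters
    ----------
    prevalence_data
        Frame with columns ``age_start``, ``value`` (proportion) and ``se``.
        At least one datapoint is required.
    csmr
        Cause-specific mortality rate per age group (deaths per person-year),
        same length as the age grid. Required.
    remission_cap
        Upper bound on the (age-constant) remission rate; the default is the
        1%/year ceiling applied to total diabetes. Set ``no_remission=True``
        for type 1 (no cure).
    smoothness
        Weight of the squared-second-difference penalty on log-rate knots.
    n_draws
        If positive, bootstrap the datapoints (resampling prevalence rows
        and parametrically perturbing the CSMR series) to produce draws.

    Returns a :class:`FitResult`; the fitted bundle's prevalence and CSMR
    are the illness-death solution of the fitted rates, so the output is
    self-consistent by construction.
    """
    age_edges = np.asarray(age_edges, dtype=float)
    n_groups = len(age_edges) - 1
    if csmr is None or np.size(csmr) == 0:
        raise ValueError("csmr series required")
    csmr_obs = np.asarray(csmr, dtype=float)
    if csmr_obs.shape != (n_groups,):
        raise ValueError("csmr must have one value per age group")
    if remission_cap < 0:
        raise ValueError("remission cap must be non-negative")
    if len(prevalence_data) < 1:
        raise ValueError("at least one prevalence datapoint required")
    m = np.broadcast_to(np.asarray(background_mortality, dtype=float), (n_groups,))

    starts = age_edges[:-1]
    group_of = {a: k for k, a in enumerate(starts)}
    try:
        dp_groups = np.array([group_of[a] for a in prevalence_data["age_start"]])
    except KeyError as err:
        raise ValueError(f"prevalence datapoint age_start {err} not on the age grid") from None
    dp_values = prevalence_data["value"].to_numpy(dtype=float)
    dp_se = np.maximum(prevalence_data["se"].to_numpy(dtype=float), 1e-4)
    csmr_se = np.maximum(csmr_obs * csmr_rel_se, 1e-7)

    knot_idx = _knot_indices(n_groups, knot_spacing)
    n_knots = len(knot_idx)

    # crude initial guesses from the data themselves
    p_init = np.full(n_groups, max(np.median(dp_values), 1e-5))
    np.put(p_init, dp_groups, np.maximum(dp_values, 1e-5))
    dp_order = np.argsort(dp_groups)
    p_interp = np.interp(
        np.arange(n_groups), dp_groups[dp_order], np.maximum(dp_values[dp_order], 1e-5)
    )
    widths = np.diff(age_edges)
    dp_da = np.gradient(p_interp, starts + widths / 2)
    i_guess = np.clip(dp_da / np.maximum(1 - p_interp, 0.1), 1e-6, 5.0)
    f_guess = np.clip(csmr_obs / np.maximum(p_interp, 1e-4), 1e-6, 5.0)

    def pack(log_i_knots, log_f_knots, log_r):
        parts = [log_i_knots, log_f_knots]
        if not no_remission:
            parts.append([log_r])
        return np.concatenate(parts)

    def unpack(theta):
        li = theta[..., :n_knots]
        lf = theta[..., n_knots : 2 * n_knots]
        lr = None if no_remission else theta[..., 2 * n_knots]
        return li, lf, lr

    def model_curves(theta):
        li, lf, lr = unpack(theta)
        i = np.exp(_interp_log(knot_idx, li, n_groups))
        f = np.exp(_interp_log(knot_idx, lf, n_groups))
        if no_remission:
            r = np.zeros_like(i)
        else:
            r = np.broadcast_to(np.exp(lr)[..., None], i.shape).copy()
        return i, r, f

    def objective_batch(theta, dp_groups, dp_values, dp_se, csmr_t, csmr_se_t):
        """Objective for theta with arbitrary leading batch dims."""
        i, r, f = model_curves(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = solve_illness_death(i, r, f, np.broadcast_to(m, i.shape), age_edges)
        p_model = sol.prevalence
        csmr_model = sol.csmr
        if np.ndim(dp_groups) == 1:
            p_at = p_model[..., dp_groups]
        else:  # per-replicate resampled datapoint indices
            idx = np.broadcast_to(dp_groups, p_model.shape[:-1] + (dp_groups.shape[-1],))
            p_at = np.take_along_axis(p_model, idx, axis=-1)
        mis_p = ((p_at - dp_values) / dp_se) ** 2
        mis_c = ((csmr_model - csmr_t) / csmr_se_t) ** 2
        li, lf, _ = unpack(theta)
        pen = np.zeros(theta.shape[:-1])
        if n_knots >= 3:
            pen = (np.diff(li, n=2, axis=-1) ** 2).sum(axis=-1) + (
                np.diff(lf, n=2, axis=-1) ** 2
            ).sum(axis=-1)
        return mis_p.sum(axis=-1) + mis_c.sum(axis=-1) + smoothness * pen

    cap_log = np.log(max(remission_cap, 1e-12))

    def fit_once(theta0, dp_g, dp_v, dp_s, csmr_t, maxiter=maxiter, fix_log_r=None):
        csmr_se_t = np.maximum(np.abs(csmr_t) * csmr_rel_se, 1e-7)
        h = 1e-6

        def fun_and_grad(theta):
            batch = np.repeat(theta[None, :], theta.size + 1, axis=0)
            batch[1:] += np.eye(theta.size) * h
            vals = objective_batch(batch, dp_g, dp_v, dp_s, csmr_t, csmr_se_t)
            return vals[0], (vals[1:] - vals[0]) / h

        bounds = [(_LOG_RATE_FLOOR, _LOG_RATE_CEIL)] * (2 * n_knots)
        if not no_remission:
            if fix_log_r is not None:
                theta0 = theta0.copy()
                theta0[-1] = fix_log_r
                bounds.append((fix_log_r, fix_log_r))
            else:
                bounds.append((_LOG_RATE_FLOOR, min(cap_log, _LOG_RATE_CEIL)))
        res = minimize(
            fun_and_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-11},
        )
        return res

    li0 = np.log(i_guess)[knot_idx]
    lf0 = np.log(f_guess)[knot_idx]
    theta0 = pack(li0, lf0, np.log(max(remission_cap, 1e-8)) - 1.0)
    best = None
    if not no_remission and profile_remission and remission_cap > 0:
        # incidence and remission trade off in a nearly flat valley; a short
        # profile over the (age-constant) remission rate resolves it
        r_grid = np.concatenate(
            [[1e-8], np.geomspace(remission_cap / 100.0, remission_cap, 7)]
        )
        warm = theta0
        for rc in r_grid:
            res_p = fit_once(warm, dp_groups, dp_values, dp_se, csmr_obs,
                             maxiter=maxiter, fix_log_r=np.log(rc))
            warm = res_p.x
            if best is None or res_p.fun < best.fun:
                best = res_p
        theta0 = best.x
    res = fit_once(theta0, dp_groups, dp_values, dp_se, csmr_obs)
    if best is not None and best.fun < res.fun:
        res = best
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"rate fit did not converge: objective={res.fun!r}, message={res.message}"
        )

    i_fit, r_fit, f_fit = model_curves(res.x)
    bundle = solve_illness_death(i_fit, r_fit, f_fit, m, age_edges)

    prevalence_draws = incidence_draws = None
    clamp_note = {}
    if n_draws > 0:
        # nonparametric bootstrap of the prevalence datapoints (CSMR series
        # perturbed parametrically); all replicates refit at once with a
        # warm-started projected Adam on the shared batched objective
        rng = np.random.default_rng(seed)
        n_dp = len(dp_values)
        take = rng.integers(0, n_dp, size=(n_draws, n_dp))
        dp_g_b = dp_groups[take][:, None, :]
        dp_v_b = dp_values[take][:, None, :]
        dp_s_b = dp_se[take][:, None, :]
        csmr_b = np.maximum(
            csmr_obs + rng.standard_normal((n_draws, n_groups)) * csmr_se, 0.0
        )[:, None, :]
        csmr_se_b = np.maximum(np.abs(csmr_b) * csmr_rel_se, 1e-7)
        n_par = res.x.size
        lo = np.full(n_par, _LOG_RATE_FLOOR)
        hi = np.full(n_par, _LOG_RATE_CEIL)
        if not no_remission:
            hi[-1] = min(cap_log, _LOG_RATE_CEIL)
        theta = np.repeat(res.x[None, :], n_draws, axis=0)
        mom = np.zeros_like(theta)
        vel = np.zeros_like(theta)
        h = 1e-6
        eye = np.eye(n_par) * h
        for t in range(1, 151):
            batch = np.repeat(theta[:, None, :], n_par + 1, axis=1)
            batch[:, 1:, :] += eye[None]
            vals = objective_batch(batch, dp_g_b, dp_v_b, dp_s_b, csmr_b, csmr_se_b)
            grad = (vals[:, 1:] - vals[:, :1]) / h
            mom = 0.9 * mom + 0.1 * grad
            vel = 0.999 * vel + 0.001 * grad * grad
            step = 0.02 * (mom / (1 - 0.9**t)) / (np.sqrt(vel / (1 - 0.999**t)) + 1e-8)
            theta = np.clip(theta - step, lo, hi)
        i_b, r_b, f_b = model_curves(theta)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol_b = solve_illness_death(
                i_b, r_b, f_b, np.broadcast_to(m, i_b.shape), age_edges
            )
        prevalence_draws = sol_b.prevalence
        incidence_draws = i_b
    return FitResult(
        bundle=bundle,
        prevalence_draws=prevalence_draws,
        incidence_draws=incidence_draws,
        objective=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success or res.status == 1),
        diagnostics=clamp_note,
    )


# ---------------------------------------------------------------------------
# type 2 by subtraction
# ---------------------------------------------------------------------------


def assign_under15_to_type1(total: DrawSet, type1: DrawSet, age_limit: float = 15.0):
    """Return a copy of *type1* with all under-``age_limit`` prevalence set to the total.

    Below the age limit every diabetes case is treated as type 1, so the
    subsequent subtraction leaves zero type 2 prevalence there.
    """
    check_aligned(total.index, type1.index, context="assign_under15_to_type1")
    young = (type1.index["age_start"] < age_limit).to_numpy()
    draws = type1.draws.copy()
    draws[young] = total.draws[young]
    return DrawSet(type1.index, draws)


def subtract_type1(total: DrawSet, type1: DrawSet):
    """Type 2 prevalence as draw-wise ``max(total - type1, 0)``.

    Returns ``(type2, n_clamped)`` where ``n_clamped`` counts the
    draw-cells floored at zero (type 1 exceeding total in that draw).
    """
    check_aligned(total.index, type1.index, context="subtract_type1")
    if total.n_draws != type1.n_draws:
        raise ValueError("draw counts differ between total and type 1")
    diff = total.draws - type1.draws
    n_clamped = int((diff < 0).sum())
    return DrawSet(total.index, np.maximum(diff, 0.0)), n_clamped
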