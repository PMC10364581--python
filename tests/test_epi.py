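import numpy as np
import pandas as pd
import pytest

from diabem import DrawSet, make_grid, solve_illness_death, subtract_type1
from diabem.containers import AlignmentError
from diabem.epi import DomainError, assign_under15_to_type1, fit_rates


def brute_force_prevalence(i, r, f, m, age_edges, steps_per_year=200, p0=0.0):
    """Independent fine-grid Runge–Kutta integration of the two-compartment
    system with piecewise-constant rates; vectorised over leading dims."""
    i, r, f, m = np.broadcast_arrays(
        np.atleast_2d(i), np.atleast_2d(r), np.atleast_2d(f), np.atleast_2d(m)
    )
    n_curves, n_groups = i.shape
    s = np.full(n_curves, 1.0 - p0)
    c = np.full(n_curves, float(p0))
    prev = np.empty((n_curves, n_groups))
    for k in range(n_groups):
        tot = s + c
        prev[:, k] = np.where(tot > 0, c / np.where(tot > 0, tot, 1.0), 0.0)
        width = age_edges[k + 1] - age_edges[k]
        n_steps = max(1, int(round(width * steps_per_year)))
        h = width / n_steps
        ik, rk, fk, mk = i[:, k], r[:, k], f[:, k], m[:, k]

        def deriv(s, c):
            return -(ik + mk) * s + rk * c, ik * s - (rk + mk + fk) * c

        for _ in range(n_steps):
            k1s, k1c = deriv(s, c)
            k2s, k2c = deriv(s + h / 2 * k1s, c + h / 2 * k1c)
            k3s, k3c = deriv(s + h / 2 * k2s, c + h / 2 * k2c)
            k4s, k4c = deriv(s + h * k3s, c + h * k3c)
            s = s + h / 6 * (k1s + 2 * k2s + 2 * k3s + k4s)
            c = c + h / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)
    return prev


class TestSolveIllnessDeath:
    def test_no_inflow_means_no_cases(self):
        edges = np.arange(0.0, 101.0, 5.0)
        n = len(edges) - 1
        z = np.zeros(n)
        out = solve_illness_death(z, z, z, np.full(n, 0.01), edges)
        assert np.all(out.prevalence == 0.0)
        assert np.all(out.csmr == 0.0)

    def test_closed_form_cumulative_incidence(self):
        # with r=f=0, p(a) = 1 - exp(-i*a)
        edges = np.arange(0.0, 101.0, 1.0)
        n = len(edges) - 1
        i = np.full(n, 0.01)
        z = np.zeros(n)
        out = solve_illness_death(i, z, z, z, edges)
        assert out.prevalence[50] == pytest.approx(1 - np.exp(-0.5), abs=1e-9)
        expected = 1 - np.exp(-0.01 * edges[:-1])
        assert np.max(np.abs(out.prevalence - expected)) < 1e-6

    def test_steady_state_prevalence(self):
        # with f=0, p converges to i/(i+r) regardless of m
        edges = np.arange(0.0, 401.0, 1.0)
        n = len(edges) - 1
        out = solve_illness_death(
            np.full(n, 0.02), np.full(n, 0.08), np.zeros(n), np.full(n, 0.013), edges
        )
        assert abs(out.prevalence[200] - 0.2) < 1e-3

    def test_consistency_residual_is_tiny(self):
        rng = np.random.default_rng(5)
        edges = np.arange(0.0, 101.0, 5.0)
        n = len(edges) - 1
        out = solve_illness_death(
            rng.uniform(0, 0.05, n), rng.uniform(0, 0.01, n),
            rng.uniform(0, 0.1, n), rng.uniform(0, 0.05, n), edges,
        )
        assert out.consistency_residual() < 1e-10

    def test_agrees_with_brute_force_integrator(self):
        rng = np.random.default_rng(17)
        edges = np.arange(0.0, 101.0, 5.0)
        n = len(edges) - 1
        i = rng.uniform(0, 0.05, (10, n))
        r = rng.uniform(0, 0.01, (10, n))
        f = rng.uniform(0, 0.10, (10, n))
        m = rng.uniform(0, 0.05, (10, n))
        out = solve_illness_death(i, r, f, m, edges)
        oracle = brute_force_prevalence(i, r, f, m, edges)
        assert np.max(np.abs(out.prevalence - oracle)) < 1e-6

    def test_prevalence_monotone_in_incidence(self):
        rng = np.random.default_rng(23)
        edges = np.arange(0.0, 101.0, 5.0)
        n = len(edges) - 1
        for _ in range(20):
            i = rng.uniform(0, 0.05, n)
            r = rng.uniform(0, 0.01, n)
            f = rng.uniform(0, 0.05, n)
            m = rng.uniform(0, 0.03, n)
            bump = rng.uniform(0, 0.02, n)
            p_lo = solve_illness_death(i, r, f, m, edges).prevalence
            p_hi = solve_illness_death(i + bump, r, f, m, edges).prevalence
            assert np.all(p_hi >= p_lo - 1e-12)

    def test_negative_rate_rejected(self):
        edges = np.array([0.0, 50.0, 100.0])
        with pytest.raises(DomainError):
            solve_illness_death([-0.01, 0.01], [0, 0], [0, 0], [0, 0], edges)

    def test_underflow_warns_and_defines_zero(self):
        edges = np.arange(0.0, 501.0, 50.0)
        n = len(edges) - 1
        with pytest.warns(RuntimeWarning, match="underflow"):
            out = solve_illness_death(
                np.zeros(n), np.zeros(n), np.zeros(n), np.full(n, 10.0), edges
            )
        assert np.all(np.isfinite(out.prevalence))


class TestFitRates:
    def test_noiseless_recovery_on_interior_age_groups(self, smooth_truth):
        t = smooth_truth
        dp = pd.DataFrame({"age_start": t["ages"], "value": t["bundle"].prevalence,
                           "se": 1e-4})
        fit = fit_rates(dp, t["bundle"].csmr, t["edges"], t["m"],
                        smoothness=1e-6, maxiter=800, csmr_rel_se=1e-3)
        interior = slice(2, 18)
        rel_i = np.abs(fit.bundle.incidence[interior] / t["i"][interior] - 1)
        rel_f = np.abs(fit.bundle.excess_mortality[interior] / t["f"][interior] - 1)
        assert rel_i.max() < 0.05
        assert rel_f.max() < 0.05
        # output is self-consistent by construction
        assert fit.bundle.consistency_residual() < 1e-10

    def test_remission_cap_is_respected_when_truth_exceeds_it(self, age_edges_20):
        edges = age_edges_20
        ages = edges[:-1]
        n = len(ages)
        i = 2e-4 * np.exp(0.03 * ages)
        r = np.full(n, 0.05)  # truth above the 1% cap
        f = 0.008 * np.exp(0.012 * ages)
        m = 5e-4 * np.exp(0.07 * ages)
        truth = solve_illness_death(i, r, f, m, edges)
        dp = pd.DataFrame({"age_start": ages, "value": truth.prevalence, "se": 1e-4})
        fit = fit_rates(dp, truth.csmr, edges, m, remission_cap=0.01, maxiter=200)
        assert np.all(fit.bundle.remission <= 0.01 + 1e-12)

    def test_no_remission_mode_pins_remission_at_zero(self, smooth_truth):
        t = smooth_truth
        dp = pd.DataFrame({"age_start": t["ages"], "value": t["bundle"].prevalence,
                           "se": 1e-3})
        fit = fit_rates(dp, t["bundle"].csmr, t["edges"], t["m"], no_remission=True,
                        maxiter=100)
        assert np.all(fit.bundle.remission == 0.0)

    def test_missing_csmr_is_an_error(self, smooth_truth):
        t = smooth_truth
        dp = pd.DataFrame({"age_start": t["ages"][:3], "value": [0.01] * 3,
                           "se": [0.001] * 3})
        with pytest.raises(ValueError, match="csmr series required"):
            fit_rates(dp, np.array([]), t["edges"], t["m"])

    def test_no_datapoints_is_an_error(self, smooth_truth):
        t = smooth_truth
        empty = pd.DataFrame({"age_start": [], "value": [], "se": []})
        with pytest.raises(ValueError, match="datapoint"):
            fit_rates(empty, t["bundle"].csmr, t["edges"], t["m"])

    def test_negative_cap_is_a_configuration_error(self, smooth_truth):
        t = smooth_truth
        dp = pd.DataFrame({"age_start": t["ages"], "value": t["bundle"].prevalence,
                           "se": 1e-3})
        with pytest.raises(ValueError, match="cap"):
            fit_rates(dp, t["bundle"].csmr, t["edges"], t["m"], remission_cap=-0.1)

    def test_bootstrap_draws_have_requested_shape(self, smooth_truth):
        t = smooth_truth
        dp = pd.DataFrame({"age_start": t["ages"], "value": t["bundle"].prevalence,
                           "se": 1e-3})
        fit = fit_rates(dp, t["bundle"].csmr, t["edges"], t["m"],
                        n_draws=12, seed=9, maxiter=60)
        assert fit.prevalence_draws.shape == (12, len(t["ages"]))
        assert np.all(fit.prevalence_draws >= 0)


class TestSubtractType1:
    def _pair(self, total_val, type1_val, n_draws=4):
        idx = make_grid(["A"], np.array([0.0, 15.0, 50.0, 100.0]), years=(2021,))
        total = DrawSet.constant(idx, np.full(len(idx), total_val), n_draws)
        type1 = DrawSet.constant(idx, np.full(len(idx), type1_val), n_draws)
        return total, type1

    def test_plain_subtraction(self):
        total, type1 = self._pair(0.10, 0.004)
        type2, n_clamped = subtract_type1(total, type1)
        assert np.allclose(type2.draws, 0.096)
        assert n_clamped == 0

    def test_floor_at_zero_is_counted(self):
        total, type1 = self._pair(0.01, 0.02)
        type2, n_clamped = subtract_type1(total, type1)
        assert np.all(type2.draws == 0.0)
        assert n_clamped == total.n_cells * total.n_draws

    def test_equal_inputs_give_zero(self):
        total, type1 = self._pair(0.05, 0.05)
        type2, _ = subtract_type1(total, type1)
        assert np.all(type2.draws == 0.0)

    def test_misaligned_grids_raise(self):
        total, type1 = self._pair(0.1, 0.01)
        other = type1.index.copy()
        other["location"] = "B"
        with pytest.raises(AlignmentError):
            subtract_type1(total, DrawSet(other, type1.draws))

    def test_under15_assignment_makes_type2_zero_below_cutoff(self):
        total, type1 = self._pair(0.08, 0.001)
        reassigned = assign_under15_to_type1(total, type1)
        type2, _ = subtract_type1(total, reassigned)
        young = (type2.index["age_start"] < 15).to_numpy()
        assert np.all(type2.draws[young] == 0.0)
        assert np.allclose(type2.draws[~young], 0.079)
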