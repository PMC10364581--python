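import numpy as np
import pandas as pd
import pytest

from diabem.forecast import (
    _expit,
    fit_forecast_model,
    forecast_counts,
    intercept_shift,
    project,
)


def simulate_history(beta1=0.08, n_strata=30, years=range(1990, 2022),
                     noise_sd=0.0, seed=0, covariate_name="bmi"):
    """Stratum-intercept logit-prevalence history driven by one covariate."""
    rng = np.random.default_rng(seed)
    rows_y, rows_x = [], []
    for g in range(n_strata):
        loc = f"loc_{g % 5}"
        age0 = float((g // 5) % 6) * 10 + 30
        sex = "male" if g % 2 else "female"
        alpha = rng.uniform(-6.0, -3.0)
        x0 = rng.uniform(22.0, 28.0)
        slope = rng.uniform(0.02, 0.08)
        for y in years:
            x = x0 + slope * (y - 1990)
            eta = beta1 * x + alpha + rng.normal(0, noise_sd)
            rows_y.append((loc, age0, age0 + 10, sex, y, _expit(eta)))
            rows_x.append((loc, age0, age0 + 10, sex, y, x))
    cols = ["location", "age_start", "age_end", "sex", "year", "value"]
    return pd.DataFrame(rows_y, columns=cols), pd.DataFrame(rows_x, columns=cols)


class TestFitForecastModel:
    @pytest.mark.parametrize("method", ["fixed", "random"])
    def test_noiseless_slope_recovered_exactly(self, method):
        hist, cov = simulate_history(beta1=0.08, noise_sd=0.0, seed=1)
        model = fit_forecast_model(hist, cov, "BMI", method=method)
        assert model.beta1 == pytest.approx(0.08, abs=1e-6)

    def test_noisy_slope_recovered_within_ten_percent(self):
        hist, cov = simulate_history(beta1=0.08, noise_sd=0.05, seed=2)
        model = fit_forecast_model(hist, cov, "BMI")
        assert abs(model.beta1 - 0.08) / 0.08 < 0.10

    def test_constant_covariate_is_unidentifiable(self):
        hist, cov = simulate_history(seed=3)
        cov["value"] = 25.0
        with pytest.raises(ValueError, match="unidentifiable|variation"):
            fit_forecast_model(hist, cov, "BMI")

    def test_short_history_rejected(self):
        hist, cov = simulate_history(years=[2020, 2021], seed=4)
        with pytest.raises(ValueError, match="3 years"):
            fit_forecast_model(hist, cov, "BMI")

    def test_missing_covariate_year_rejected(self):
        hist, cov = simulate_history(seed=5)
        cov = cov[cov["year"] != 2000]
        with pytest.raises(ValueError, match="missing"):
            fit_forecast_model(hist, cov, "BMI")


class TestProject:
    def test_inverse_logit_at_zero_is_half(self):
        hist, cov = simulate_history(seed=6)
        model = fit_forecast_model(hist, cov, "BMI", method="fixed")
        model.beta1 = 1.0
        model.alphas["alpha"] = 0.0
        cov0 = cov.copy()
        cov0["value"] = 0.0
        out = project(model, cov0)
        assert np.allclose(out["value"], 0.5)

    def test_constant_covariate_gives_flat_projection(self):
        hist, cov = simulate_history(seed=7)
        model = fit_forecast_model(hist, cov, "BMI", method="fixed")
        frozen = cov[cov["year"] == 2021].copy()
        frames = []
        for y in range(2021, 2031):
            f = frozen.copy()
            f["year"] = y
            frames.append(f)
        out = project(model, pd.concat(frames))
        per_stratum = out.groupby(["location", "age_start", "sex"])["value"].nunique()
        assert (per_stratum == 1).all()

    def test_monotone_covariate_monotone_projection(self):
        hist, cov = simulate_history(seed=8)
        model = fit_forecast_model(hist, cov, "BMI", method="fixed")
        assert model.beta1 > 0
        out = project(model, cov)
        for _, g in out.groupby(["location", "age_start", "sex"]):
            v = g.sort_values("year")["value"].to_numpy()
            assert np.all(np.diff(v) >= -1e-12)

    def test_unseen_stratum_is_an_error(self):
        hist, cov = simulate_history(seed=9)
        model = fit_forecast_model(hist, cov, "BMI", method="fixed")
        cov_new = cov.copy()
        cov_new["location"] = "atlantis"
        with pytest.raises(ValueError, match="unseen"):
            project(model, cov_new)


class TestInterceptShift:
    def _projection(self):
        hist, cov = simulate_history(seed=10)
        model = fit_forecast_model(hist, cov, "BMI", method="fixed")
        return project(model, cov), hist

    def test_zero_offset_when_already_aligned(self):
        proj, _ = self._projection()
        anchored = intercept_shift(proj, proj, anchor_year=2021)
        assert np.allclose(anchored["value"], proj["value"], atol=1e-12)

    def test_additive_offset_applied_to_all_years(self):
        proj, _ = self._projection()
        est = proj[proj["year"] == 2021].copy()
        est["value"] = est["value"] + 0.02
        anchored = intercept_shift(proj, est, anchor_year=2021)
        merged = anchored.merge(proj, on=["location", "age_start", "sex", "year"],
                                suffixes=("_new", "_old"))
        assert np.allclose(merged["value_new"] - merged["value_old"], 0.02, atol=1e-12)

    def test_anchoring_is_exact(self):
        proj, hist = self._projection()
        est = hist[hist["year"] == 2021]
        anchored = intercept_shift(proj, est, anchor_year=2021)
        check = anchored[anchored["year"] == 2021].merge(
            est.rename(columns={"value": "target"}),
            on=["location", "age_start", "sex"],
        )
        assert np.max(np.abs(check["value"] - check["target"])) < 1e-12

    def test_clamping_above_one_is_counted(self):
        proj, _ = self._projection()
        est = proj[proj["year"] == 2021].copy()
        est["value"] = 1.5  # force the shift through the ceiling
        anchored = intercept_shift(proj, est, anchor_year=2021)
        assert anchored["value"].max() <= 1.0
        assert anchored.attrs["n_clamped"] > 0

    def test_misaligned_grids_rejected(self):
        proj, hist = self._projection()
        est = hist[(hist["year"] == 2021) & (hist["location"] != "loc_0")]
        with pytest.raises(ValueError, match="misaligned|missing"):
            intercept_shift(proj, est, anchor_year=2021)


class TestForecastCounts:
    def _pop(self, prev, value=1_000_000.0):
        pop = prev[["location", "age_start", "age_end", "sex", "year"]].copy()
        pop["value"] = value
        return pop

    def test_product_rule(self):
        prev = pd.DataFrame([
            ("A", 40.0, 50.0, "female", 2050, 0.10)
        ], columns=["location", "age_start", "age_end", "sex", "year", "value"])
        out = forecast_counts(prev, self._pop(prev))
        assert out.loc[0, "cases"] == pytest.approx(100_000.0)

    def test_zero_population_zero_cases(self):
        prev = pd.DataFrame([
            ("A", 40.0, 50.0, "female", 2050, 0.10)
        ], columns=["location", "age_start", "age_end", "sex", "year", "value"])
        out = forecast_counts(prev, self._pop(prev, value=0.0))
        assert out.loc[0, "cases"] == 0.0

    def test_aggregation_is_not_rate_of_aggregate_unless_uniform(self):
        prev = pd.DataFrame([
            ("A", 40.0, 50.0, "female", 2050, 0.10),
            ("A", 50.0, 60.0, "female", 2050, 0.30),
        ], columns=["location", "age_start", "age_end", "sex", "year", "value"])
        pop = self._pop(prev)
        pop["value"] = [1e6, 3e6]
        out = forecast_counts(prev, pop)
        summed = out["cases"].sum()
        naive = prev["value"].mean() * pop["value"].sum()
        assert summed != pytest.approx(naive)
        # but with uniform prevalence the two agree
        prev2 = prev.copy()
        prev2["value"] = 0.2
        out2 = forecast_counts(prev2, pop)
        assert out2["cases"].sum() == pytest.approx(0.2 * pop["value"].sum())
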