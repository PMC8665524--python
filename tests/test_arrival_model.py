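import numpy as np
import pandas as pd
import pytest

from phenotrack.arrival_model import (
    LmmSpec,
    annotate_arrivals,
    build_design,
    derive_covariates,
    fit_gaussian_lmm,
    fit_lmm_ou,
    marginal_r2,
    ou_correlation,
    predict_delta_arrival,
)
from phenotrack.synthetic_data import ArrivalSimConfig, simulate_arrival_dataset


@pytest.fixture(scope="module")
def sim_dataset():
    return simulate_arrival_dataset(ArrivalSimConfig(), seed=42)


class TestOuKernel:
    def test_lag_zero_correlation_is_one(self):
        C = ou_correlation(np.array([100.0, 105.0, 111.0]), rho=5.0)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_decay(self):
        C = ou_correlation(np.array([0.0, 5.0]), rho=5.0)
        assert C[0, 1] == pytest.approx(np.exp(-1.0))

    def test_rho_zero_identity(self):
        C = ou_correlation(np.array([0.0, 1.0, 2.0]), rho=0.0)
        np.testing.assert_array_equal(C, np.eye(3))


@pytest.fixture(scope="module")
def small_grid_records():
    from phenotrack.phenology import PhenologyGrid
    from phenotrack.synthetic_data import TemperatureConfig, simulate_temperature

    cfg = TemperatureConfig(
        lons=(10.0, 11.0), lats=(50.0,), years=(2018,), crossing_base=100.0
    )
    da, _ = simulate_temperature(cfg, seed=0)
    grid = PhenologyGrid.from_hourly(da, climatology_years=(2018, 2018))
    records = pd.DataFrame(
        {
            "individual_id": ["a", "a"],
            "year": [2018, 2018],
            "site_id": [1, 2],
            "arrival_doy": [120, 140],
            "lon": [10.05, 10.9],
            "lat": [50.0, 50.0],
            "proj_x": [400.0, 500.0],
            "proj_y": [0.0, 0.0],
            "cum_distance_km": [300.0, 700.0],
        }
    )
    return records, grid


class TestAnnotate:
    def test_delta_and_drop(self, small_grid_records):
        records, grid = small_grid_records
        out = annotate_arrivals(records, grid)
        assert (out["delta_arrival_d"] == out["arrival_doy"] - out["tgs_onset"]).all()

    def test_onset_100_arrival_120(self, small_grid_records):
        records, grid = small_grid_records
        out = annotate_arrivals(records, grid)
        row = out.iloc[0]
        assert row["tgs_onset"] == 100.0
        assert row["arrival_doy"] == 120
        assert row["delta_arrival_d"] == 20.0


class TestAnnotateVariants:
    def test_gdd_at_arrival_matches_hand_sum(self, small_grid_records):
        records, grid = small_grid_records
        out = annotate_arrivals(records, grid)
        row = out.iloc[0]  # onset 100, arrival 120
        daily = grid.annotate(row["lon"], row["lat"], 2018)["daily"]
        expected = sum(max(0.0, t - 5.0) for t in daily[99:120])  # days 100..120
        assert row["gdd_at_arrival"] == pytest.approx(expected, abs=1e-9)

    def test_undefined_onset_dropped(self):
        from phenotrack.phenology import PhenologyGrid
        from phenotrack.synthetic_data import TemperatureConfig, simulate_temperature

        # crossing far beyond the onset search window -> undefined onset
        cfg = TemperatureConfig(
            lons=(10.0,), lats=(50.0,), years=(2018,), crossing_base=400.0
        )
        da, _ = simulate_temperature(cfg, seed=0)
        grid = PhenologyGrid.from_hourly(da, climatology_years=(2018, 2018))
        records = pd.DataFrame(
            {
                "individual_id": ["a"],
                "year": [2018],
                "site_id": [1],
                "arrival_doy": [120],
                "lon": [10.0],
                "lat": [50.0],
                "proj_x": [400.0],
                "proj_y": [0.0],
                "cum_distance_km": [300.0],
            }
        )
        out = annotate_arrivals(records, grid)
        assert out.empty


class TestModelVariants:
    def test_max_latitude_predictor(self, sim_dataset):
        df, _ = sim_dataset
        df = df.assign(max_latitude_scaled=df["max_longitude_scaled"] * 0.9)
        fit = fit_lmm_ou(df, variant="full", predictor="max_latitude")
        assert "max_latitude" in fit.fe_names
        assert any(n.startswith("max_latitude:distance") for n in fit.fe_names)

    def test_gdd_response_column(self, sim_dataset):
        df, _ = sim_dataset
        df = df.assign(gdd_at_arrival_scaled=df["delta_arrival_d_scaled"])
        fit = fit_lmm_ou(df, variant="full", response="gdd_at_arrival_scaled")
        ref = fit_lmm_ou(df, variant="full")
        np.testing.assert_allclose(fit.beta, ref.beta, atol=1e-8)

    def test_unknown_predictor_rejected(self, sim_dataset):
        df, _ = sim_dataset
        with pytest.raises(ValueError, match="predictor"):
            build_design(df, "full", predictor="altitude")


class TestCovariates:
    def _records(self):
        return pd.DataFrame(
            {
                "individual_id": ["a", "a", "b"],
                "year": [2018, 2018, 2018],
                "arrival_doy": [100, 120, 110],
                "proj_x": [400.0, 900.0, 600.0],
                "cum_distance_km": [300.0, 700.0, 500.0],
                "delta_arrival_d": [10.0, 25.0, 15.0],
                "tgs_deviation": [1.0, 1.0, -2.0],
            }
        )

    def test_distance_traveled(self):
        df, _ = derive_covariates(self._records())
        assert df["distance_traveled"].tolist() == [300.0, 700.0, 500.0]

    def test_max_longitude_per_group(self):
        df, _ = derive_covariates(self._records())
        assert df["max_longitude"].tolist() == [900.0, 900.0, 600.0]

    def test_end_location_raises_max(self):
        df, _ = derive_covariates(self._records(), end_proj_x={("a", 2018): 1500.0})
        assert df["max_longitude"].tolist() == [1500.0, 1500.0, 600.0]

    def test_scaled_columns_standardized(self):
        df, scaling = derive_covariates(self._records())
        for col in ("delta_arrival_d", "tgs_deviation", "max_longitude"):
            z = df[col + "_scaled"]
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)
            assert col in scaling


class TestLmmAgainstOls:
    def test_no_random_structure_equals_ols(self, sim_dataset):
        df, _ = sim_dataset
        X, names = build_design(df, "full")
        y = df["delta_arrival_d_scaled"].to_numpy()
        spec = LmmSpec(
            include_individual=False, include_individual_year=False, include_ou=False
        )
        idy = np.array([f"{i}/{y_}" for i, y_ in zip(df["individual_id"], df["year"])])
        fit = fit_gaussian_lmm(
            y, X, names, df["individual_id"].to_numpy(), idy, spec=spec
        )
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)  # independent oracle
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_ou_limit_matches_independent_model(self, sim_dataset):
        # likelihood with rho -> 0 equals the independent-residual model
        # with the residual variance split across the two terms
        df, _ = sim_dataset
        from phenotrack.arrival_model import _blocks, _profiled_negloglik

        X, names = build_design(df, "full")
        y = df["delta_arrival_d_scaled"].to_numpy()
        idy = np.array([f"{i}/{y_}" for i, y_ in zip(df["individual_id"], df["year"])])
        t = df["arrival_doy"].to_numpy(dtype=float)
        blocks = _blocks(df["individual_id"].to_numpy(), idy)

        spec_ou = LmmSpec()
        lt = np.log([0.1, 0.1, 0.15, 1e-8, 0.15])  # s2i, s2iy, s2ou, rho, s2e
        nll_ou, _, _ = _profiled_negloglik(lt, y, X, blocks, idy, t, spec_ou)

        spec_ind = LmmSpec(include_ou=False)
        lt2 = np.log([0.1, 0.1, 0.30])  # s2ou folds into the residual
        nll_ind, _, _ = _profiled_negloglik(lt2, y, X, blocks, idy, None, spec_ind)
        assert nll_ou == pytest.approx(nll_ind, abs=1e-6)


class TestFitRecovery:
    def test_fixed_effect_recovery_large_n(self):
        cfg = ArrivalSimConfig(n_individuals=150, events_per_group=7)
        df, truth = simulate_arrival_dataset(cfg, seed=7)
        assert len(df) >= 1000
        fit = fit_lmm_ou(df, variant="full")
        for name, est, se in zip(fit.fe_names, fit.beta, fit.se):
            true = truth["beta"][name]
            # single-seed estimate: bound by sampling error, not bias alone
            assert abs(est - true) < 4.0 * se + 0.02, name

    def test_z_invariant_under_response_rescaling(self, sim_dataset):
        df, _ = sim_dataset
        fit1 = fit_lmm_ou(df, variant="full")
        df2 = df.copy()
        df2["delta_arrival_d_scaled"] = df2["delta_arrival_d_scaled"] * 7.3
        fit2 = fit_lmm_ou(df2, variant="full")
        # agreement limited by optimizer termination, not by the theory
        np.testing.assert_allclose(fit1.z, fit2.z, rtol=1e-3)

    def test_ci_brackets_estimate(self, sim_dataset):
        df, _ = sim_dataset
        fit = fit_lmm_ou(df, variant="full")
        assert np.all(fit.ci_low < fit.beta)
        assert np.all(fit.beta < fit.ci_high)
        assert all(v >= 0 for v in fit.varcomp.values())

    def test_last_arrival_variant(self, sim_dataset):
        df, _ = sim_dataset
        fit = fit_lmm_ou(df, variant="last_arrival")
        assert fit.fe_names == ["intercept", "tgs_deviation", "max_longitude"]
        n_groups = df.groupby(["individual_id", "year"]).ngroups
        assert len(fit.fitted_fixed) == n_groups

    def test_too_few_groups(self):
        df = pd.DataFrame(
            {
                "individual_id": ["a"] * 3,
                "year": [2018] * 3,
                "capture_site": ["NLD"] * 3,
                "arrival_doy": [100, 110, 120],
                "tgs_deviation_scaled": [0.0, 0.0, 0.0],
                "max_longitude_scaled": [0.1, 0.1, 0.1],
                "distance_traveled_scaled": [0.0, 0.5, 1.0],
                "delta_arrival_d_scaled": [0.0, 0.2, 0.4],
            }
        )
        with pytest.raises(ValueError, match="two groups"):
            fit_lmm_ou(df, variant="full")


class TestMarginalR2:
    def _fit_with(self, var_f, var_re, var_rest):
        from phenotrack.arrival_model import LmmFit

        rng = np.random.default_rng(0)
        fitted = rng.normal(0, np.sqrt(var_f), 5000) if var_f else np.zeros(5000)
        # set the empirical variance exactly
        if var_f:
            fitted = (fitted - fitted.mean()) / fitted.std(ddof=0) * np.sqrt(var_f)
        return LmmFit(
            fe_names=["x"],
            beta=np.array([1.0]),
            se=np.array([0.1]),
            ci_low=np.array([0.8]),
            ci_high=np.array([1.2]),
            z=np.array([10.0]),
            varcomp={"s2_individual": var_re, "s2_ou": var_rest / 2, "s2_resid": var_rest / 2},
            ou_range=1.0,
            loglik=0.0,
            converged=True,
            spec=LmmSpec(),
            fitted_fixed=fitted,
        )

    def test_quarter(self):
        assert marginal_r2(self._fit_with(1.0, 1.0, 2.0)) == pytest.approx(0.25)

    def test_zero_fixed_variance(self):
        assert marginal_r2(self._fit_with(0.0, 1.0, 2.0)) == 0.0

    def test_all_variance_fixed(self):
        assert marginal_r2(self._fit_with(1.0, 0.0, 0.0)) == 1.0

    def test_bounded(self, sim_dataset):
        df, _ = sim_dataset
        fit = fit_lmm_ou(df, variant="full")
        assert 0.0 <= marginal_r2(fit) <= 1.0


class TestPrediction:
    def _toy_fit(self):
        from phenotrack.arrival_model import LmmFit

        return LmmFit(
            fe_names=[
                "intercept[LTU]",
                "intercept[NLD]",
                "tgs_deviation",
                "max_longitude",
                "max_longitude:distance_traveled[LTU]",
                "max_longitude:distance_traveled[NLD]",
            ],
            beta=np.array([1.0, 2.0, -0.5, -1.0, -0.2, -0.3]),
            se=np.ones(6),
            ci_low=np.zeros(6),
            ci_high=np.zeros(6),
            z=np.ones(6),
            varcomp={},
            ou_range=1.0,
            loglik=0.0,
            converged=True,
            spec=LmmSpec(),
            scaling={},  # identity scaling
        )

    def test_hand_computed_linear_predictor(self):
        fit = self._toy_fit()
        scen = pd.DataFrame(
            {
                "capture_site": ["NLD"],
                "max_longitude": [2.0],
                "distance_traveled": [1.0],
                "tgs_deviation": [1.0],
            }
        )
        # 2.0 + (-0.5)(1) + (-1.0)(2) + (-0.3)(2)(1) = -1.1
        assert predict_delta_arrival(fit, scen)[0] == pytest.approx(-1.1)

    def test_monotone_in_longitude_with_negative_coef(self):
        fit = self._toy_fit()
        scen = pd.DataFrame(
            {
                "capture_site": ["NLD"] * 3,
                "max_longitude": [0.0, 1.0, 2.0],
                "distance_traveled": [1.0] * 3,
                "tgs_deviation": [0.0] * 3,
            }
        )
        pred = predict_delta_arrival(fit, scen)
        assert pred[0] > pred[1] > pred[2]

    def test_back_transform_uses_stored_scaling(self):
        fit = self._toy_fit()
        fit.scaling = {"delta_arrival_d": (20.0, 10.0)}
        scen = pd.DataFrame(
            {
                "capture_site": ["NLD"],
                "max_longitude": [0.0],
                "distance_traveled": [0.0],
                "tgs_deviation": [0.0],
            }
        )
        # eta = 2.0 on the z-scale -> 20 + 10 * 2 = 40 days
        assert predict_delta_arrival(fit, scen)[0] == pytest.approx(40.0)

    def test_out_of_context_scenario_warns(self):
        fit = self._toy_fit()
        fit.scaling = {"max_longitude": (0.0, 1.0), "delta_arrival_d": (0.0, 1.0)}
        scen = pd.DataFrame(
            {
                "capture_site": ["NLD"],
                "max_longitude": [50.0],
                "distance_traveled": [0.0],
                "tgs_deviation": [0.0],
            }
        )
        with pytest.warns(UserWarning, match="outside"):
            predict_delta_arrival(fit, scen)
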