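import numpy as np
import pandas as pd
import pytest

from carpop.model_core import PatientParameters, derived_outputs, simulate
from carpop.population import ParamDistribution, PopulationModel
from carpop.sensitivity import (DUMMY_NAME, SensitivityResult,
                                bounds_from_population, efast_design,
                                efast_indices, evaluate_outputs,
                                local_sensitivity, model_output_fn,
                                normalize_heatmap, rf_importance,
                                spearman_sensitivity)
from carpop.synthetic_data import default_patient


@pytest.fixture(scope="module")
def additive_design():
    return efast_design({"x1": (0.0, 1.0), "x2": (0.0, 1.0)},
                        samples_per_param=1000, resamplings=4,
                        include_dummy=True, seed=1)


class TestEfastDesign:
    def test_row_count(self):
        bounds = {f"p{i}": (0.0, 1.0) for i in range(46)}
        d = efast_design(bounds, 1000, 4, include_dummy=True, seed=0)
        assert d.X.shape == (188_000, 47)

    def test_dummy_column_appended_with_unit_bounds(self, additive_design):
        assert additive_design.names[-1] == DUMMY_NAME
        assert additive_design.X[:, -1].min() >= 0.0
        assert additive_design.X[:, -1].max() <= 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_rows_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        lo, width = rng.uniform(-5, 5, 3), rng.uniform(0.1, 10, 3)
        bounds = {f"p{i}": (lo[i], lo[i] + width[i]) for i in range(3)}
        d = efast_design(bounds, 129, 2, include_dummy=False, seed=seed)
        for j, name in enumerate(d.names):
            assert d.X[:, j].min() >= bounds[name][0]
            assert d.X[:, j].max() <= bounds[name][1]

    def test_too_small_sample_reports_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            efast_design({"x": (0, 1)}, samples_per_param=64, resamplings=1)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            efast_design({"x": (1.0, 1.0)}, 1000)


class TestEfastIndices:
    def test_additive_variance_shares(self, additive_design):
        # y = x1 + x2 with equal uniform ranges: each main effect owns half
        y = additive_design.X[:, 0] + additive_design.X[:, 1]
        si, tsi = efast_indices(additive_design, y)
        assert si[0] == pytest.approx(0.5, abs=0.05)
        assert si[1] == pytest.approx(0.5, abs=0.05)
        assert np.all(tsi >= si - 0.02)

    def test_interaction_only_model(self, additive_design):
        y = ((additive_design.X[:, 0] - 0.5)
             * (additive_design.X[:, 1] - 0.5))
        si, tsi = efast_indices(additive_design, y)
        assert tsi[0] > si[0] + 0.5

    def test_null_parameter_at_dummy_level(self, additive_design):
        y = additive_design.X[:, 0]
        si, _ = efast_indices(additive_design, y)
        assert si[1] < si[2] + 0.02  # x2 indistinguishable from the dummy

    def test_constant_output_warns_zero(self, additive_design):
        with pytest.warns(UserWarning, match="constant"):
            si, tsi = efast_indices(additive_design,
                                    np.ones(len(additive_design.X)))
        assert np.all(si == 0) and np.all(tsi == 0)

    def test_nan_imputation_bounded(self, additive_design):
        y = additive_design.X[:, 0] + additive_design.X[:, 1]
        y[:10] = np.nan
        si, _ = efast_indices(additive_design, y)
        assert si[0] == pytest.approx(0.5, abs=0.05)
        y[: int(0.02 * len(y))] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            efast_indices(additive_design, y)


class TestRfImportance:
    def test_importances_form_distribution(self):
        rng = np.random.default_rng(0)
        X = rng.random((200, 4))
        y = X[:, 1] + 0.5 * X[:, 2]
        imp = rf_importance(X, y, seed=0)
        assert imp.sum() == pytest.approx(1.0)
        assert np.all(imp >= 0)

    def test_single_feature_target(self):
        rng = np.random.default_rng(1)
        X = rng.random((500, 4))
        imp = rf_importance(X, X[:, 3], seed=0)
        assert imp[3] > 0.9

    def test_pure_noise_calibration(self):
        rng = np.random.default_rng(2)
        X = rng.random((2000, 5))
        y = rng.random(2000)
        imp = rf_importance(X, y, seed=0)
        assert imp.max() < 2.0 / 5.0

    def test_constant_output_uniform(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="constant"):
            imp = rf_importance(rng.random((100, 4)), np.ones(100))
        assert np.allclose(imp, 0.25)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            rf_importance(np.ones((10, 2)), np.ones(10))


class TestSpearman:
    def test_monotone_relation(self):
        x = np.linspace(0, 1, 50)
        rho = spearman_sensitivity(x[:, None], np.exp(3 * x))
        assert rho[0] == pytest.approx(1.0)

    def test_hand_ranks(self):
        X = np.array([[3.0], [1.0], [2.0]])
        y = np.array([9.0, 1.0, 4.0])
        assert spearman_sensitivity(X, y)[0] == pytest.approx(1.0)

    def test_independent_null_bound(self):
        rng = np.random.default_rng(5)
        X = rng.random((1000, 1))
        rho = spearman_sensitivity(X, rng.random(1000))
        assert abs(rho[0]) < 0.1


class TestLocalSensitivity:
    def test_linear_output_scores_exactly_one_percent(self):
        def fn(p):
            return {"y": 3.0 * p.rho0, "z": 42.0}

        M = local_sensitivity([default_patient()], fn, ["rho0"])
        assert M.loc["y", "rho0"] == pytest.approx(0.01)
        assert M.loc["z", "rho0"] == 0.0

    def test_matches_central_finite_difference(self, daily_grid):
        # blood-only CAR model: d(cmax)/d(delta) from a tight central stencil
        p = default_patient()
        fn = model_output_fn(daily_grid, model_id=2)
        M = local_sensitivity([p], fn, ["delta"])
        h = 1e-5 * p.delta
        up = fn(p.replace(delta=p.delta + h))["cmax"]
        dn = fn(p.replace(delta=p.delta - h))["cmax"]
        base = fn(p)["cmax"]
        expected = abs((up - dn) / (2 * h)) * p.delta / base * 0.01
        assert M.loc["cmax", "delta"] == pytest.approx(expected, rel=0.05)


class TestNormalizeHeatmap:
    def test_dummy_subtract_and_scale(self):
        M = pd.DataFrame([[0.5, 0.3, 0.1]], index=["cmax"],
                         columns=["a", "b", DUMMY_NAME])
        (out,) = normalize_heatmap([SensitivityResult("eFAST-SI", M,
                                                      has_dummy=True)])
        assert out.matrix.loc["cmax", "a"] == pytest.approx(1.0)
        assert out.matrix.loc["cmax", "b"] == pytest.approx(0.5)
        assert DUMMY_NAME not in out.matrix.columns

    def test_row_equal_to_dummy_goes_to_zero(self):
        M = pd.DataFrame([[0.1, 0.1, 0.1]], index=["cmax"],
                         columns=["a", "b", DUMMY_NAME])
        (out,) = normalize_heatmap([SensitivityResult("eFAST-SI", M,
                                                      has_dummy=True)])
        assert np.all(out.matrix.to_numpy() == 0.0)

    def test_no_dummy_scaling_only(self):
        M = pd.DataFrame([[0.4, 0.2]], index=["cmax"], columns=["a", "b"])
        (out,) = normalize_heatmap([SensitivityResult("local", M)])
        assert out.matrix.loc["cmax", "a"] == 1.0
        assert out.matrix.loc["cmax", "b"] == 0.5

    def test_signed_entries_use_magnitude(self):
        M = pd.DataFrame([[-0.8, 0.4]], index=["cmax"], columns=["a", "b"])
        (out,) = normalize_heatmap([SensitivityResult("SRC-vpop", M)])
        assert out.matrix.loc["cmax", "a"] == 1.0


class TestModelFacingHelpers:
    def test_bounds_from_population(self):
        pop = PopulationModel(params={
            "rho0": ParamDistribution("lognormal", np.log(0.5), 0.2),
            "phi": ParamDistribution("lognormal", np.log(0.25), 0.0),
            "pi_car0_naive": ParamDistribution("logitnormal", 0.0, 3.0),
        })
        b = bounds_from_population(pop, k_sd=3.0)
        assert "phi" not in b           # zero spread: nothing to sweep
        lo, hi = b["rho0"]
        assert lo == pytest.approx(0.5 * np.exp(-0.6))
        assert hi == pytest.approx(0.5 * np.exp(0.6))
        plo, phi_ = b["pi_car0_naive"]
        assert 0 < plo < phi_ < 1

    def test_evaluate_outputs_ignores_dummy_column(self, daily_grid):
        base = default_patient()
        X = np.array([[base.rho0, 0.3], [base.rho0 * 1.1, 0.9]])
        out = evaluate_outputs(X, ["rho0", DUMMY_NAME], base, daily_grid)
        assert len(out) == 2
        assert set(out.columns) >= {"cmax", "tmax", "auc"}
        assert out.cmax[1] > out.cmax[0]
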