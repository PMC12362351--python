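import warnings

import numpy as np
import pandas as pd
import pytest

from carpop.fitting import (FitResult, correlate_covariate,
                            decompose_proliferation, fit_individual,
                            fit_population, fit_sequential,
                            interpolate_tumour_burden, rank_responders)
from carpop.model_core import model1_closed_form, simulate
from carpop.population import ParamDistribution, PopulationModel, draw_vpop
from carpop.synthetic_data import default_patient, default_truth_population


def model1_obs(p, days=None):
    days = np.arange(31.0) if days is None else np.asarray(days, float)
    vals = model1_closed_form(p, days)
    return pd.DataFrame({"patient_id": "X", "time_day": days,
                         "observable": "E_blood", "value": vals})


class TestFitIndividual:
    def test_model1_noise_free_recovery(self):
        truth = default_patient().replace(rho0=0.7, gamma=0.1, delta=0.18,
                                          E0=2e8)
        init = default_patient()
        fr = fit_individual(1, model1_obs(truth), init, n_restarts=1)
        for name in ("rho0", "gamma", "delta", "E0"):
            assert getattr(fr.params, name) == pytest.approx(
                getattr(truth, name), rel=0.01), name

    def test_frozen_parameter_untouched(self):
        truth = default_patient().replace(rho0=0.7, gamma=0.1)
        init = default_patient().replace(delta=truth.delta)
        fr = fit_individual(1, model1_obs(truth), init, frozen=("delta",),
                            n_restarts=1)
        assert fr.params.delta == init.delta
        assert "delta" not in fr.provenance

    def test_degenerate_ridge_constant_counts(self):
        # flat counts force net growth ~ 0: rho_e(t) ~ delta with a ridge
        obs = pd.DataFrame({"patient_id": "X", "time_day": np.arange(31.0),
                            "observable": "E_blood", "value": 1e8})
        init = default_patient().replace(rho0=1e-3, gamma=1e-3, E0=1e8)
        fr = fit_individual(1, obs, init, n_restarts=1)
        assert fr.objective < 1e-6
        net0 = fr.params.rho0 * np.exp(-0.0) - fr.params.delta
        assert abs(net0) < 1e-3

    def test_missing_observable_rejected(self):
        obs = pd.DataFrame({"patient_id": "X", "time_day": [0.0],
                            "observable": "C_blood", "value": [1e6]})
        with pytest.raises(ValueError):
            fit_individual(1, obs, default_patient())


class TestFitSequential:
    def test_noise_free_end_to_end_recovery(self, dense_noise_free_patient):
        ds, pid = dense_noise_free_patient
        truth = ds.truth_params(pid)
        fr = fit_sequential(ds.patient_observations(pid), default_patient(),
                            n_restarts=1, seed=0)
        tf, ff = truth.to_flat(), fr.params.to_flat()
        for name, tv in tf.items():
            if tv == 0:
                continue
            assert abs(ff[name] - tv) / abs(tv) < 0.05, name

    def test_model1_params_equal_model1_only_fit(self, dense_noise_free_patient):
        ds, pid = dense_noise_free_patient
        obs = ds.patient_observations(pid)
        solo = fit_individual(1, obs, default_patient(), n_restarts=1, seed=1)
        full = fit_sequential(obs, default_patient(), n_restarts=1, seed=0)
        for name in ("rho0", "gamma", "delta", "E0"):
            assert getattr(full.params, name) == getattr(solo.params, name)

    def test_missing_lesion_data_skips_lesion_layers(self,
                                                     dense_noise_free_patient):
        ds, pid = dense_noise_free_patient
        obs = ds.patient_observations(pid)
        obs = obs[obs.observable != "spd"]
        fr = fit_sequential(obs, default_patient(), n_restarts=1, seed=0)
        assert set(fr.layers_fit) == {1, 2, 4}

    def test_provenance_records_owning_layer(self, dense_noise_free_patient):
        ds, pid = dense_noise_free_patient
        fr = fit_sequential(ds.patient_observations(pid), default_patient(),
                            n_restarts=1, seed=0)
        assert fr.provenance["rho0"] == 1
        assert fr.provenance["C0"] == 3      # ownership passes from layer 2
        assert fr.provenance["kappa_shared"] == 3
        assert fr.provenance["pi_car0"] == 5


class TestFitPopulation:
    def _fits(self, patients):
        prov = {"rho0": 1, "gamma": 1, "delta": 1, "C0": 3}
        return [FitResult(params=p, objective=0.0, provenance=dict(prov))
                for p in patients]

    def test_identical_individuals_degenerate(self):
        fits = self._fits([default_patient()] * 4)
        with pytest.warns(UserWarning, match="degenerate"):
            pop = fit_population(fits)
        for name in ("rho0", "gamma", "delta", "C0"):
            assert pop.params[name].scale == 0.0
        assert pop.params["rho0"].transform(0.0) == pytest.approx(
            default_patient().rho0)

    def test_lognormal_location_recovery(self):
        truth = PopulationModel(params={
            "C0": ParamDistribution("lognormal", np.log(1000.0), 0.5)})
        draws = draw_vpop(truth, 64, 21, default_patient())
        pop = fit_population(self._fits(draws))
        est = pop.params["C0"]
        se = est.scale / np.sqrt(64)
        assert abs(est.location - np.log(1000.0)) < 3 * se

    def test_latent_correlation_recovery(self):
        names = ["rho0", "C0"]
        R = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=names, columns=names)
        truth = PopulationModel(params={
            "rho0": ParamDistribution("lognormal", np.log(0.5), 0.3),
            "C0": ParamDistribution("lognormal", np.log(1e6), 0.5),
        }, correlation=R)
        draws = draw_vpop(truth, 200, 8, default_patient())
        pop = fit_population(self._fits(draws), correlate=names)
        assert abs(pop.correlation.loc["rho0", "C0"] - 0.9) < 0.1

    def test_too_few_fits_rejected(self):
        with pytest.raises(ValueError):
            fit_population(self._fits([default_patient()]))


class TestDecomposeProliferation:
    def test_endogenous_at_time_zero_is_rho0(self, params, daily_grid):
        traj = simulate(3, params, daily_grid)
        dec = decompose_proliferation(params, traj)
        assert dec.endogenous[0] == pytest.approx(params.rho0)

    def test_no_tumour_no_antigen_drive(self, params, daily_grid):
        p = params.replace(B0=1e-30)
        traj = simulate(3, p, daily_grid)
        dec = decompose_proliferation(p, traj)
        assert np.allclose(dec.antigen, 0.0, atol=1e-12)

    def test_saturation_limit(self, params, daily_grid):
        # B >> K_half throughout: antigen-driven rate ~ rho_a
        p = params.replace(B0=1e14, K_half=1e9, kappa_p=np.zeros(4))
        traj = simulate(3, p, daily_grid)
        dec = decompose_proliferation(p, traj)
        assert np.all(np.abs(dec.antigen - p.rho_a) / p.rho_a < 0.01)

    def test_blood_compartment_has_no_antigen_drive(self, params, daily_grid):
        traj = simulate(3, params, daily_grid)
        dec = decompose_proliferation(params, traj, compartment="blood")
        assert np.all(dec.antigen == 0.0)

    def test_lesion_needs_tumour_state(self, params, daily_grid):
        traj = simulate(1, params, daily_grid)
        with pytest.raises(ValueError):
            decompose_proliferation(params, traj)


class TestRankResponders:
    def test_month6_breaks_ties(self):
        outcomes = [("a", (0, 0, 2)), ("b", (0, 0, 1))]
        order, good, poor = rank_responders(outcomes)
        assert order == ["b", "a"]

    def test_stable_for_full_ties(self):
        outcomes = [(i, (1, 1, 1)) for i in range(4)]
        order, good, poor = rank_responders(outcomes)
        assert order == [0, 1, 2, 3]
        assert good == [0, 1] and poor == [2, 3]

    def test_month1_dominates(self):
        outcomes = [("a", (3, 0, 0)), ("b", (2, 3, 3)), ("c", (0, 3, 3)),
                    ("d", (1, 0, 0))]
        order, _, _ = rank_responders(outcomes)
        assert order == ["c", "d", "b", "a"]

    def test_odd_n_warns_extra_to_poor(self):
        outcomes = [(i, (i, 0, 0)) for i in range(5)]
        with pytest.warns(UserWarning, match="odd"):
            _, good, poor = rank_responders(outcomes)
        assert len(good) == 2 and len(poor) == 3


class TestCorrelateCovariate:
    def test_identity_and_negation(self):
        t = np.arange(5.0)
        r = np.array([5.0, 4.0, 3.0, 2.5, 1.0])
        rhos, med = correlate_covariate({"p": (t, r)}, {"p": (t, r)})
        assert rhos["p"] == pytest.approx(1.0)
        rhos, med = correlate_covariate({"p": (t, r)}, {"p": (t, -r)})
        assert rhos["p"] == pytest.approx(-1.0)

    def test_rank_arithmetic(self):
        t = np.arange(3.0)
        rhos, med = correlate_covariate(
            {"p": (t, np.array([3.0, 1.0, 2.0]))},
            {"p": (t, np.array([30.0, 10.0, 20.0]))})
        assert rhos["p"] == pytest.approx(1.0)
        assert med == pytest.approx(1.0)

    def test_too_few_shared_points_skipped(self):
        t = np.arange(5.0)
        r = np.linspace(1, 2, 5)
        with pytest.raises(ValueError):
            correlate_covariate({"p": (t, r)}, {"p": ([0.0, 1.0], [1.0, 2.0])})


class TestInterpolateTumourBurden:
    def test_endpoints_map_exactly(self):
        spd = interpolate_tumour_burden(10.0, 2.0, [0, 10, 20, 28],
                                        [100, 70, 40, 20])
        assert spd[0] == 10.0 and spd[-1] == 2.0

    def test_affine_example(self):
        spd = interpolate_tumour_burden(10.0, 2.0, [0, 7, 14, 28],
                                        [100.0, 80.0, 60.0, 20.0])
        assert np.allclose(spd, [10.0, 8.0, 6.0, 2.0])

    def test_linear_ldh_gives_linear_spd(self):
        t = np.linspace(0, 28, 8)
        ldh = 300 - 5 * t
        spd = interpolate_tumour_burden(9.0, 3.0, t, ldh)
        assert np.allclose(np.diff(spd, 2), 0.0, atol=1e-12)

    def test_constant_ldh_falls_back_to_time(self):
        with pytest.warns(UserWarning, match="linear-in-time"):
            spd = interpolate_tumour_burden(10.0, 2.0, [0, 14, 28],
                                            [50.0, 60.0, 50.0])
        assert np.allclose(spd, [10.0, 6.0, 2.0])

    def test_negative_spd_rejected(self):
        with pytest.raises(ValueError):
            interpolate_tumour_burden(-1.0, 2.0, [0, 1], [1.0, 2.0])
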