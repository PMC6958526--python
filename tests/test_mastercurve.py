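"""Empirical master curve, forward prediction and the inverse (E, nu, D) fit."""

import numpy as np
import pytest
from scipy.optimize import brentq
from sklearn.base import clone

import poroindent as pi
from poroindent.core import DegenerateParameterError, DomainError
from poroindent.mastercurve import (
    UnderdeterminedError,
    normalized_max_force_definition,
    unit_crossing_tau,
)


class TestEmpiricalMaster:
    @pytest.mark.parametrize("tau, expected", [
        (0.0, 12.5),
        (1.0, 0.9009808),
        (100.0, 0.1294206),  # 12.5*exp(-2.63*100**0.12), direct evaluation
    ])
    def test_values(self, tau, expected):
        assert pi.empirical_master(tau) == pytest.approx(expected, rel=1e-6)

    def test_unit_crossing(self):
        # independent root solve of A exp(-b tau^p) = 1
        tau0 = brentq(lambda x: pi.empirical_master(x) - 1.0, 1e-6, 1e3,
                      xtol=1e-14)
        assert unit_crossing_tau() == pytest.approx(tau0, rel=1e-10)
        assert tau0 == pytest.approx(0.713824, rel=1e-5)

    def test_strictly_decreasing_and_positive(self):
        tau = np.geomspace(1e-6, 1e4, 300)
        v = pi.empirical_master(tau)
        assert np.all(np.diff(v) < 0)
        assert np.all(v > 0)

    def test_clamp(self):
        assert pi.empirical_master(0.1, clamp=True) == 1.0
        assert pi.empirical_master(2.0, clamp=True) == pi.empirical_master(2.0)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            pi.empirical_master(-0.1)


class TestNormalizedMaxForce:
    def test_affine_definition(self):
        assert normalized_max_force_definition(2.0, 3.0, 1.0) == pytest.approx(0.5)
        assert normalized_max_force_definition(1.0, 3.0, 1.0) == 0.0
        assert normalized_max_force_definition(3.0, 3.0, 1.0) == 1.0
        with pytest.raises(DegenerateParameterError):
            normalized_max_force_definition(2.0, 1.0, 1.0)

    def test_hertz_limit_endpoints(self, macro_params, geometry75):
        delta_M = 3e-3
        f_inst, f_drained = pi.limit_forces(geometry75.R, delta_M,
                                            macro_params.E, macro_params.nu)
        lo = pi.normalized_max_force(
            pi.RampObservation(geometry75, 1.0, delta_M, f_drained),
            macro_params.E, macro_params.nu)
        hi = pi.normalized_max_force(
            pi.RampObservation(geometry75, 1.0, delta_M, f_inst),
            macro_params.E, macro_params.nu)
        assert lo == pytest.approx(0.0, abs=1e-12)
        assert hi == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_through_forward_model(self, geometry75):
        # pick tau so the empirical value is ~0.37, then invert exactly
        params = pi.MaterialParams(1e4, 0.3, 1e-8)
        target = 0.37
        tau = brentq(lambda x: pi.empirical_master(x) - target, 0.72, 1e4)
        delta_M = 1e-3
        t_R = tau * geometry75.R * delta_M / params.D
        F = pi.predict_FM(t_R, delta_M, geometry75, params)
        obs = pi.RampObservation(geometry75, t_R, delta_M, F)
        back = pi.normalized_max_force(obs, params.E, params.nu)
        assert back == pytest.approx(target, abs=1e-12)


class TestPredictFM:
    def test_limits(self, geometry75):
        params = pi.MaterialParams(1e4, 0.3, 1e-9)
        delta_M = 1e-3
        f_inst, f_drained = pi.limit_forces(geometry75.R, delta_M, params.E,
                                            params.nu)
        # huge rise time: drained; tiny: clamped to instantaneous
        assert pi.predict_FM(1e12, delta_M, geometry75, params) == pytest.approx(
            f_drained, rel=1e-3)
        assert pi.predict_FM(1e-9, delta_M, geometry75, params) == pytest.approx(
            f_inst, rel=1e-12)

    def test_clamp_region_yields_instantaneous_force(self, macro_params,
                                                     geometry75):
        # tau_R = 0.2222 lies below the unit crossing, so the raw empirical
        # value (~1.39) is clamped and the prediction is the undrained limit
        F = pi.predict_FM(100.0, 3e-3, geometry75, macro_params)
        f_inst, _ = pi.limit_forces(geometry75.R, 3e-3, macro_params.E,
                                    macro_params.nu)
        assert F == pytest.approx(f_inst, rel=1e-12)
        raw = pi.predict_FM(100.0, 3e-3, geometry75, macro_params, clamp=False)
        assert raw > F

    def test_force_decreases_with_rise_time(self, geometry75):
        params = pi.MaterialParams(1e4, 0.3, 1e-8)
        t = np.geomspace(1.0, 1e6, 60)
        F = np.array([pi.predict_FM(ti, 1e-3, geometry75, params) for ti in t])
        assert np.all(np.diff(F) <= 1e-15)


class TestPredictDeltaM:
    def test_drained_closed_form(self, geometry75):
        params = pi.MaterialParams(1e4, 0.3, 1e-9)
        F = 0.05
        delta = pi.predict_deltaM(1e15, F, geometry75, params)
        closed = (3 * F * (1 - params.nu ** 2) /
                  (4 * np.sqrt(geometry75.R) * params.E)) ** (2 / 3)
        assert delta == pytest.approx(closed, rel=1e-6)

    def test_instantaneous_closed_form(self, geometry75):
        params = pi.MaterialParams(1e4, 0.3, 1e-9)
        F = 0.05
        delta = pi.predict_deltaM(1e-12, F, geometry75, params)
        closed = (3 * F * 0.75 /
                  (4 * np.sqrt(geometry75.R) * params.E)) ** (2 / 3)
        assert delta == pytest.approx(closed, rel=1e-6)

    def test_round_trip(self, geometry75):
        params = pi.MaterialParams(1e4, 0.3, 1e-8)
        for t_R in [10.0, 300.0, 1e4]:
            delta = pi.predict_deltaM(t_R, 0.02, geometry75, params)
            assert pi.predict_FM(t_R, delta, geometry75, params) == pytest.approx(
                0.02, rel=1e-8)

    def test_depth_grows_with_rise_time(self, geometry75):
        # slower ramps look softer: larger depth to reach the same force
        params = pi.MaterialParams(1e4, 0.3, 1e-8)
        t = np.geomspace(10.0, 1e5, 20)
        d = [pi.predict_deltaM(ti, 0.02, geometry75, params) for ti in t]
        assert all(b >= a - 1e-15 for a, b in zip(d, d[1:]))

    def test_unreachable_force_rejected(self, geometry75):
        params = pi.MaterialParams(1e4, 0.3, 1e-9)
        with pytest.raises(DomainError):
            pi.predict_deltaM(1.0, 1e9, geometry75, params)


class TestFit:
    def test_underdetermined_too_few(self, geometry75):
        obs = [pi.RampObservation(geometry75, 10.0, 1e-3, 0.1),
               pi.RampObservation(geometry75, 20.0, 1e-3, 0.1)]
        with pytest.raises(UnderdeterminedError):
            pi.fit_poroelastic(obs, {"n_boot": 0})

    def test_underdetermined_single_rise_time(self, geometry75):
        obs = [pi.RampObservation(geometry75, 10.0, d, 0.1 * d / 1e-3)
               for d in (1e-3, 2e-3, 3e-3)]
        with pytest.raises(UnderdeterminedError):
            pi.fit_poroelastic(obs, {"n_boot": 0})

    def test_noiseless_macro_recovery(self, paam_params):
        proto = pi.emulate_paper_protocols("macro_paam")
        obs = pi.simulate_ramp_suite(paam_params, proto)
        res = pi.fit_poroelastic(obs, {"n_boot": 0})
        assert res.params.E == pytest.approx(paam_params.E, rel=1e-3)
        assert res.params.nu == pytest.approx(paam_params.nu, abs=1e-3)
        assert res.params.D == pytest.approx(paam_params.D, rel=1e-2)
        assert res.rms < 1e-6

    def test_order_invariance(self, afm_suite_noiseless):
        rng = np.random.default_rng(0)
        shuffled = list(afm_suite_noiseless)
        rng.shuffle(shuffled)
        a = pi.fit_poroelastic(afm_suite_noiseless, {"n_boot": 0})
        b = pi.fit_poroelastic(shuffled, {"n_boot": 0})
        assert a.params.E == pytest.approx(b.params.E, rel=1e-9)
        assert a.params.D == pytest.approx(b.params.D, rel=1e-9)

    def test_dataframe_input(self, afm_suite_noiseless, afm_params):
        import pandas as pd
        df = pd.DataFrame({
            "R": [o.geometry.R for o in afm_suite_noiseless],
            "t_R": [o.t_R for o in afm_suite_noiseless],
            "delta_M": [o.delta_M for o in afm_suite_noiseless],
            "F_M": [o.F_M for o in afm_suite_noiseless],
        })
        est = pi.PoroelasticMasterCurveFit(n_boot=0).fit(df)
        assert est.E_ == pytest.approx(afm_params.E, rel=1e-3)
        pred = est.predict(df)
        np.testing.assert_allclose(pred, df["F_M"], rtol=1e-6)

    def test_bootstrap_uncertainty_reported(self, afm_params):
        from dataclasses import replace
        proto = replace(pi.emulate_paper_protocols("afm_agarose06"),
                        noise=pi.NoiseSpec(sigma_F_rel=0.01), seed=3)
        obs = pi.simulate_ramp_suite(afm_params, proto)
        res = pi.fit_poroelastic(obs, {"n_boot": 25, "random_state": 0})
        assert set(res.uncertainty) >= {"E", "nu", "D"}
        assert res.uncertainty["E"] > 0

    def test_sklearn_clone_compatible(self):
        est = pi.PoroelasticMasterCurveFit(n_boot=7, random_state=5)
        c = clone(est)
        assert c.get_params()["n_boot"] == 7
        assert c.get_params()["random_state"] == 5


class TestMasterCurveTable:
    def test_table_shape_and_columns(self, afm_suite_noiseless):
        res = pi.fit_poroelastic(afm_suite_noiseless, {"n_boot": 0})
        tab = pi.master_curve_table(res)
        assert len(tab) == len(afm_suite_noiseless)
        np.testing.assert_allclose(
            tab["F_star_empirical"],
            pi.empirical_master(tab["tau_R"].to_numpy(), clamp=True))
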