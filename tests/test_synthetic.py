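"""Glucose kinetics, sensor response, protocol set, and movie rendering."""

import dataclasses

import numpy as np
import pytest

from glucofret import (CellSpec, Ellipse, KineticParams, Protocol,
                       ProtocolEvent, SceneParams, SensorParams,
                       default_params, default_scene, render_movie,
                       sensor_ratio, simulate_glucose, standard_protocols,
                       steady_state_glucose)
from glucofret.imaging import extract_trace, ratio_stack


def params(**overrides) -> KineticParams:
    base = dict(v_transport=0.1, k_transport=1.0, v_glycolysis=0.02,
                v_ppp=0.015, v_hbp_max=0.03, k_consume=0.02,
                tau_hk_inhibition=18.0, tau_hbp_transient=8.0)
    base.update(overrides)
    return KineticParams(**base)


def constant_protocol(gext, duration=30.0, **event_kw):
    return Protocol((ProtocolEvent(0.0, gext, **event_kw),), duration_min=duration)


class TestProtocol:
    def test_validation(self):
        with pytest.raises(ValueError):
            Protocol((), duration_min=10)
        with pytest.raises(ValueError):  # first event not at 0
            Protocol((ProtocolEvent(5.0, 2.5),), duration_min=10)
        with pytest.raises(ValueError):  # times not increasing
            Protocol((ProtocolEvent(0, 2.5), ProtocolEvent(0, 10)), duration_min=10)
        with pytest.raises(ValueError):  # negative glucose
            Protocol((ProtocolEvent(0, -1.0),), duration_min=10)
        with pytest.raises(ValueError):  # event beyond duration
            Protocol((ProtocolEvent(0, 2.5), ProtocolEvent(20, 10)), duration_min=10)

    def test_standard_protocol_set(self):
        protos = standard_protocols()
        assert set(protos) == {"step10", "restriction", "iaa", "six_an", "combined"}
        for name, p in protos.items():
            # every protocol holds a >= 10 min baseline at 2.5 mM
            assert p.stimulus_time_min >= 10.0
            assert p.events[0].glucose_mM == 2.5
        assert protos["step10"].events[1].glucose_mM == 10.0
        assert protos["step10"].duration_min - protos["step10"].stimulus_time_min == 50.0
        assert protos["restriction"].events[1].glucose_mM == 0.2
        post = (protos["restriction"].duration_min
                - protos["restriction"].stimulus_time_min)
        assert post >= 20.0
        comb = protos["combined"].events[1]
        assert comb.iaa and comb.six_an

    def test_sampling_grid(self):
        p = constant_protocol(2.5, duration=1.0)
        assert np.allclose(p.sample_times_min(), [0, 0.25, 0.5, 0.75, 1.0])


class TestSimulateGlucose:
    def test_zero_consumption_rises_to_bath_equilibrium(self):
        kin = params(v_transport=0.5, v_glycolysis=0, v_ppp=0, v_hbp_max=0)
        tr = simulate_glucose(kin, constant_protocol(2.5, duration=600.0), g0=0.0)
        assert np.all(np.diff(tr.glucose_mM) >= -1e-12)  # monotone rise
        assert tr.glucose_mM[-1] == pytest.approx(2.5, abs=1e-3)

    def test_no_transport_is_monotone_depletion_with_mass_balance(self):
        kin = params(v_transport=0.0)
        g0 = 1.5
        tr = simulate_glucose(kin, constant_protocol(0.0, duration=30.0), g0=g0)
        assert np.all(np.diff(tr.glucose_mM) <= 1e-12)
        # independent mass balance: integrate the consumption flux over the
        # returned series and compare with the drop in the pool
        demand = kin.v_glycolysis + kin.v_ppp
        flux = demand * tr.glucose_mM / (kin.k_consume + tr.glucose_mM)
        consumed = np.trapezoid(flux, tr.time_min)
        assert consumed == pytest.approx(g0 - tr.glucose_mM[-1], abs=2e-4)

    def test_linear_regime_matches_analytic_relaxation(self):
        # G, Gext << K: dG/dt = a - b G with a = v_t Gext / Kt,
        # b = v_t/Kt + v_c/Kc -> G(t) = a/b + (g0 - a/b) exp(-b t)
        kin = params(v_transport=0.2, k_transport=1e4, v_glycolysis=0.05,
                     v_ppp=0.05, k_consume=1e4, v_hbp_max=0.0)
        gext, g0 = 1e-3, 2e-4
        tr = simulate_glucose(kin, constant_protocol(gext, duration=60.0), g0=g0)
        a = kin.v_transport * gext / kin.k_transport
        b = (kin.v_transport / kin.k_transport
             + (kin.v_glycolysis + kin.v_ppp) / kin.k_consume)
        expected = a / b + (g0 - a / b) * np.exp(-b * tr.time_min)
        assert np.allclose(tr.glucose_mM, expected, rtol=1e-6, atol=0)

    def test_restriction_is_strictly_decreasing_after_switch(self, protocols, nontg):
        kin, _ = nontg
        g0 = steady_state_glucose(kin, 2.5)
        tr = simulate_glucose(kin, protocols["restriction"], g0=g0)
        post = tr.glucose_mM[tr.time_min > 10.0]
        assert np.all(np.diff(post) < 0)

    def test_increasing_bath_glucose_never_decreases_pool(self):
        kin = params()
        lo = simulate_glucose(kin, constant_protocol(1.0, duration=60.0), g0=0.5)
        hi = simulate_glucose(kin, constant_protocol(4.0, duration=60.0), g0=0.5)
        assert np.all(hi.glucose_mM >= lo.glucose_mM - 1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_glucose(params(), constant_protocol(2.5), g0=-1.0)
        with pytest.raises(ValueError):
            params(v_transport=-0.1)

    def test_divergence_raises_not_nan(self):
        # absurd rate vs 1 s step drives RK4 unstable: explicit error
        kin = params(v_transport=1e9, k_transport=1e-6)
        with pytest.raises(RuntimeError):
            simulate_glucose(kin, constant_protocol(10.0, duration=30.0), g0=0.0)


class TestSensor:
    def test_anchor_points(self):
        s = SensorParams(k_d=0.7, r_min=1.0, r_max=2.0)
        assert sensor_ratio(0.0, s) == pytest.approx(1.0)
        assert sensor_ratio(0.7, s) == pytest.approx(1.5)  # half saturation
        # 10 mM nearly saturates: fractional occupancy 10/10.7
        frac = (sensor_ratio(10.0, s) - s.r_min) / (s.r_max - s.r_min)
        assert frac == pytest.approx(10 / 10.7, abs=1e-12)

    def test_monotone_and_bounded(self):
        s = SensorParams(k_d=0.7, r_min=0.8, r_max=2.4)
        g = np.linspace(0, 50, 500)
        r = sensor_ratio(g, s)
        assert np.all(np.diff(r) > 0)
        assert r[0] >= s.r_min and np.all(r < s.r_max)

    def test_negative_glucose_rejected(self):
        with pytest.raises(ValueError):
            sensor_ratio(-0.1, SensorParams())
        with pytest.raises(ValueError):
            SensorParams(r_min=2.0, r_max=1.0)


class TestDefaults:
    def test_yaml_defaults_load(self):
        kin, sensor = default_params("nonTg")
        assert kin.hbp_transient_scale == 0.0  # non-transgenic: no transient flux
        kin3, _ = default_params("3xTgAD")
        assert kin3.glycolysis_scale > 1.0 and kin3.ppp_scale < 1.0
        assert sensor.k_d == pytest.approx(0.7)


class TestRenderMovie:
    def make_scene(self, n_cells=2, **overrides):
        return default_scene(n_cells, 20, seed=5, **overrides)

    def test_constant_ratio_extracted_exactly(self):
        ts = np.arange(20) * 15.0
        scene = self.make_scene()
        stack, truth = render_movie(scene, np.full((2, 20), 1.2), ts)
        ratios = ratio_stack(stack)
        for roi in truth.rois:
            tr = extract_trace(ratios, roi, ts)
            assert np.allclose(tr.R, 1.2, atol=1e-9)

    def test_donor_bleach_follows_closed_form(self):
        ts = np.arange(20) * 15.0
        b = 0.012  # fraction/min, donor only
        scene = self.make_scene(1, bleach=(b, 0.0))
        stack, truth = render_movie(scene, np.full((1, 20), 1.3), ts)
        tr = extract_trace(ratio_stack(stack), truth.rois[0], ts)
        expected = 1.3 / (1.0 - b * ts / 60.0)
        assert np.allclose(tr.R, expected, atol=1e-3)

    def test_same_seed_bit_identical(self):
        ts = np.arange(20) * 15.0
        scene = self.make_scene(noise_scale=(0.5, 0.5), read_noise=1.0,
                                artifact_prob=0.2)
        r = np.full((2, 20), 1.2)
        s1, _ = render_movie(scene, r, ts)
        s2, _ = render_movie(scene, r, ts)
        assert np.array_equal(s1.donor, s2.donor)
        assert np.array_equal(s1.acceptor, s2.acceptor)

    def test_different_seed_differs(self):
        ts = np.arange(20) * 15.0
        r = np.full((2, 20), 1.2)
        s1, _ = render_movie(self.make_scene(noise_scale=(0.5, 0.5)), r, ts)
        scene2 = dataclasses.replace(self.make_scene(noise_scale=(0.5, 0.5)), seed=6)
        s2, _ = render_movie(scene2, r, ts)
        assert not np.array_equal(s1.donor, s2.donor)

    def test_overlapping_somata_rejected(self):
        cell = CellSpec(soma=Ellipse(30, 30, 12, 12),
                        nucleus=Ellipse(30, 30, 4, 4))
        other = CellSpec(soma=Ellipse(38, 30, 12, 12),
                         nucleus=Ellipse(38, 30, 4, 4))
        with pytest.raises(ValueError, match="overlap"):
            SceneParams(shape=(64, 64), cells=(cell, other))

    def test_nucleus_outside_soma_rejected(self):
        with pytest.raises(ValueError, match="nucleus"):
            CellSpec(soma=Ellipse(30, 30, 8, 8), nucleus=Ellipse(39, 30, 4, 4))

    def test_trace_count_mismatch_rejected(self):
        ts = np.arange(20) * 15.0
        with pytest.raises(ValueError):
            render_movie(self.make_scene(2), np.full((3, 20), 1.2), ts)


class TestGenotypeShapeContract:
    """Under glycolysis inhibition the Alzheimer-model genotype shows a
    biphasic dip-then-rise, the control genotype a monotone rise."""

    def test_iaa_biphasic_vs_monotone(self, protocols, nontg, tg3x, baseline,
                                      make_relative_trace):
        rel_non = make_relative_trace(*nontg, protocols["iaa"], baseline)
        rel_3x = make_relative_trace(*tg3x, protocols["iaa"], baseline)
        assert np.nanmin(rel_non.value_pct) >= -0.5  # never below baseline
        post = rel_3x.value_pct[rel_3x.time_min >= 10.0]
        i_min = int(np.argmin(post))
        assert post[i_min] < -0.5  # global minimum below baseline
        assert i_min < len(post) - 1  # ...and before the final value
        assert post[-1] > post[i_min]  # recovery after the dip

    def test_combined_inhibition_dip_deeper_in_3xtg(self, protocols, nontg,
                                                    tg3x, baseline,
                                                    make_relative_trace):
        rel_non = make_relative_trace(*nontg, protocols["combined"], baseline)
        rel_3x = make_relative_trace(*tg3x, protocols["combined"], baseline)
        assert np.nanmin(rel_3x.value_pct) < np.nanmin(rel_non.value_pct)
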