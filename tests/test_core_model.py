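"""Unit and property tests for the single-hemisphere model definition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sleepswitch as ss
from sleepswitch.core_model import (
    SECONDS_PER_HOUR,
    flip_flop_fixed_points,
    load_params,
    save_params,
)


class TestFiringRate:
    def test_midpoint_is_half_maximum(self, human_params):
        assert ss.firing_rate(human_params.theta, human_params) == pytest.approx(50.0)

    def test_saturation_limits(self, human_params):
        assert ss.firing_rate(-1e3, human_params) == pytest.approx(0.0, abs=1e-12)
        assert ss.firing_rate(1e3, human_params) == pytest.approx(human_params.Q_max)

    def test_three_quarter_point(self, human_params):
        # Q(theta + sigma'*ln 3) = Q_max/(1 + 1/3) = 0.75*Q_max
        v = human_params.theta + human_params.sigma_prime * math.log(3.0)
        assert ss.firing_rate(v, human_params) == pytest.approx(0.75 * human_params.Q_max)

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        p = ss.SwitchParams()
        q1, q2 = ss.firing_rate(v1, p), ss.firing_rate(v2, p)
        assert 0.0 <= q1 <= p.Q_max
        if v1 < v2:
            assert q1 <= q2
        if v2 - v1 > 1e-9:
            assert q1 < q2

    def test_nonfinite_potential_rejected(self, human_params):
        with pytest.raises(ValueError):
            ss.firing_rate(float("nan"), human_params)
        with pytest.raises(ValueError):
            ss.firing_rate(float("inf"), human_params)


class TestCircadianDrive:
    def test_value_at_origin(self):
        p = ss.SwitchParams(phi=0.0)
        assert ss.circadian_drive(0.0, p) == pytest.approx(p.nu_vc_c0 + p.circ_amp)

    @given(st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_24h_periodicity(self, t):
        p = ss.SwitchParams()
        assert ss.circadian_drive(t, p) == pytest.approx(
            ss.circadian_drive(t + 24.0, p), abs=1e-9
        )

    def test_nocturnal_phase_shift_flips_oscillation(self):
        diurnal = ss.SwitchParams(phi=0.0)
        nocturnal = ss.SwitchParams(phi=math.pi)
        for t in np.linspace(0, 24, 17):
            osc_d = ss.circadian_drive(t, diurnal) - diurnal.nu_vc_c0
            osc_n = ss.circadian_drive(t, nocturnal) - nocturnal.nu_vc_c0
            assert osc_d == pytest.approx(-osc_n, abs=1e-9)


class TestVlpoDrive:
    def test_reduces_to_mean_drive(self):
        p = ss.SwitchParams(circ_amp=0.0)
        assert ss.vlpo_drive(0.0, 3.0, p) == pytest.approx(p.nu_vc_c0)

    def test_homeostatic_weight_is_one_mv_per_nm(self):
        # Calibrated nu_vh = 1.0 mV/nM: one nM adds one mV.
        p = ss.SwitchParams(circ_amp=0.0)
        assert ss.vlpo_drive(1.0, 0.0, p) - ss.vlpo_drive(0.0, 0.0, p) == pytest.approx(1.0)

    @given(st.floats(0.01, 50), st.floats(0, 48))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_h(self, h, t):
        p = ss.SwitchParams()
        assert ss.vlpo_drive(2 * h, t, p) - ss.vlpo_drive(h, t, p) == pytest.approx(
            p.nu_vh * h, rel=1e-9
        )

    def test_negative_somnogen_rejected(self, human_params):
        with pytest.raises(ValueError):
            ss.vlpo_drive(-0.1, 0.0, human_params)


class TestDerivatives:
    def test_fixed_point_identity(self):
        """At a fixed point of the frozen flip-flop the vector field vanishes
        and V_m equals the VLPO-inhibited MA input."""
        p = ss.SwitchParams(circ_amp=0.0)
        for fp in flip_flop_fixed_points(1.5, p):
            # Freeze H at the self-consistent level for this drive and absorb
            # the mismatch into a shifted mean drive so D_v stays 1.5.
            q_m = ss.firing_rate(fp["V_m"], p)
            h_star = p.mu * q_m
            p_shift = p.replace(nu_vc_c0=1.5 - p.nu_vh * h_star)
            s = ss.HemiState(V_m=fp["V_m"], V_v=fp["V_v"], H=h_star)
            dvm, dvv, dh = ss.derivatives(s, 0.0, p_shift)
            assert dvm == pytest.approx(0.0, abs=1e-6)
            assert dvv == pytest.approx(0.0, abs=1e-6)
            assert dh == pytest.approx(0.0, abs=1e-9)
            assert fp["V_m"] == pytest.approx(
                p.nu_mv * ss.firing_rate(fp["V_v"], p) + p.A_drive
            )

    def test_time_units_of_tau(self, human_params):
        # tau is specified in seconds and must act in hours inside the field.
        assert human_params.tau_m_h == pytest.approx(
            human_params.tau_m / SECONDS_PER_HOUR
        )
        s = ss.HemiState(V_m=3.0, V_v=-5.0, H=10.0)
        slow = human_params.replace(tau_m=20.0)
        d_fast = ss.derivatives(s, 0.0, human_params)[0]
        d_slow = ss.derivatives(s, 0.0, slow)[0]
        assert d_fast == pytest.approx(2.0 * d_slow)

    def test_wake_firing_gives_h_equilibrium_near_22nM(self):
        """Sustained wake-level MA firing (~5/s) with mu = 4.4 nM.s drives the
        isolated homeostatic equation to ~22 nM."""
        p = ss.SwitchParams()
        q_wake = 5.0
        h_star = p.mu * q_wake
        assert h_star == pytest.approx(22.0)
        # dH/dt vanishes exactly there and is restoring around it.
        v_wake = p.theta + p.sigma_prime * math.log(q_wake / (p.Q_max - q_wake))
        s = ss.HemiState(V_m=v_wake, V_v=-30.0, H=h_star)
        assert ss.derivatives(s, 0.0, p)[2] == pytest.approx(0.0, abs=1e-9)
        s_low = ss.HemiState(V_m=v_wake, V_v=-30.0, H=h_star - 5)
        s_high = ss.HemiState(V_m=v_wake, V_v=-30.0, H=h_star + 5)
        assert ss.derivatives(s_low, 0.0, p)[2] > 0 > ss.derivatives(s_high, 0.0, p)[2]


class TestHomeostaticRelaxation:
    def test_closed_form_exponential_relaxation(self):
        """With the MA group pinned at saturation the somnogen follows
        H(t) = mu*Q_m + (H0 - mu*Q_m) exp(-t/chi) exactly; the integrator
        must reproduce the closed form."""
        # Pin MA on: huge constant drive, negligible VLPO influence.
        p = ss.SwitchParams(A_drive=200.0, nu_mv=-1e-9, chi=5.0, mu=0.05)
        cfg = ss.SimConfig(duration=20.0, transient_discard=0.0, dt=10.0)
        h0 = 30.0
        sim = ss.simulate(p, cfg, init=ss.HemiState(V_m=200.0, V_v=-10.0, H=h0))
        h_inf = p.mu * p.Q_max
        expected = h_inf + (h0 - h_inf) * np.exp(-sim.times / p.chi)
        assert np.allclose(sim.H, expected, atol=5e-3)


class TestBistability:
    def test_flip_flop_is_bistable_at_intermediate_drive(self):
        """For intermediate constant VLPO drive the frozen switch has two
        stable fixed points (wake-like and sleep-like) separated by a saddle;
        extreme drives leave a single state."""
        p = ss.SwitchParams()
        fps = flip_flop_fixed_points(1.7, p)
        stable = [f for f in fps if f["stable"]]
        assert len(fps) == 3 and len(stable) == 2
        wake, sleep = max(stable, key=lambda f: f["V_m"]), min(stable, key=lambda f: f["V_m"])
        assert ss.firing_rate(wake["V_m"], p) > 1.0   # MA active
        assert ss.firing_rate(sleep["V_m"], p) < 1.0  # MA silent
        # Monostable extremes: strong inhibition -> wake only; strong drive -> sleep only.
        assert len(flip_flop_fixed_points(-10.0, p)) == 1
        assert len(flip_flop_fixed_points(10.0, p)) == 1


class TestBoundedness:
    @given(st.floats(-30, 30), st.floats(-30, 30), st.floats(0, 40))
    @settings(max_examples=10, deadline=None)
    def test_trajectories_stay_in_invariant_box(self, v_m, v_v, h):
        p = ss.SwitchParams()
        cfg = ss.SimConfig(duration=48.0, transient_discard=0.0)
        sim = ss.simulate(p, cfg, init=ss.HemiState(V_m=v_m, V_v=v_v, H=h))
        v_m_bound = abs(p.A_drive) + abs(p.nu_mv) * p.Q_max
        d_max = p.nu_vh * max(h, p.mu * p.Q_max) + abs(p.nu_vc_c0) + abs(p.circ_amp)
        v_v_bound = d_max + abs(p.nu_vm) * p.Q_max
        margin = max(abs(v_m), abs(v_v))  # initial condition may start outside
        assert np.all(np.abs(sim.V_m) <= v_m_bound + margin + 1e-6)
        assert np.all(np.abs(sim.V_v) <= v_v_bound + margin + 1e-6)
        assert np.all(sim.H >= 0.0)


class TestParamsValidationAndIO:
    @pytest.mark.parametrize("bad", [
        {"Q_max": -1.0},
        {"sigma_prime": 0.0},
        {"nu_mv": 0.5},
        {"nu_vh": -1.0},
        {"chi": 0.0},
        {"tau_v": -10.0},
        {"sigma_noise": -0.1},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ss.SwitchParams(**bad)

    def test_yaml_round_trip(self, tmp_path, human_params):
        path = tmp_path / "params.yaml"
        save_params(human_params, path)
        assert load_params(path) == human_params

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("Q_max: 100\nbogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_params(path)

    def test_presets_resolve(self):
        assert ss.get_preset("human_nominal").chi == 45.0
        with pytest.raises(KeyError):
            ss.get_preset("unicorn")
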