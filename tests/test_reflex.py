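"""Reflex laws, delay buffer, phase gating and stimulation bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reflexgait.reflex import (
    U_MIN,
    DelayBuffer,
    LegPhase,
    SensorySample,
    compute_stimulations,
    force_feedback,
    length_feedback,
    pd_stimulation,
    sample_delayed,
    simbicon_hip_target,
    update_phase,
)
from reflexgait.registry import MUSCLES, ParameterVector


def make_buffer(samples):
    buf = DelayBuffer()
    for s in samples:
        buf.push(s)
    return buf


def random_sample(rng, t):
    return SensorySample(
        time=t,
        muscle_force={m: float(rng.uniform(0, 2)) for m in MUSCLES},
        muscle_length={m: float(rng.uniform(0.5, 1.5)) for m in MUSCLES},
        theta_t=float(rng.uniform(-0.5, 0.5)),
        theta_h=float(rng.uniform(-1, 1)),
        theta_k=float(rng.uniform(0, 3)),
        theta_t_dot=float(rng.uniform(-2, 2)),
        theta_h_dot=float(rng.uniform(-2, 2)),
        theta_k_dot=float(rng.uniform(-2, 2)),
        v_x=float(rng.uniform(0, 2)),
        d=float(rng.uniform(-0.3, 0.3)),
    )


class TestDelayBuffer:
    def test_constant_signal_returns_constant(self):
        buf = make_buffer(
            [SensorySample(time=t, v_x=0.7) for t in np.arange(0, 0.1, 0.005)]
        )
        assert sample_delayed(buf, 0.08, 0.02).v_x == 0.7

    def test_ramp_delay_lookup(self):
        dt = 0.005
        buf = make_buffer(
            [SensorySample(time=t, v_x=t) for t in np.arange(0, 0.2, dt)]
        )
        got = sample_delayed(buf, 0.1, 0.02).v_x
        assert abs(got - 0.08) <= dt + 1e-12

    def test_holds_first_sample_before_history(self):
        buf = make_buffer([SensorySample(time=0.0, v_x=0.42)])
        assert sample_delayed(buf, 0.0, 0.02).v_x == 0.42

    def test_empty_buffer_is_state_error(self):
        with pytest.raises(RuntimeError):
            sample_delayed(DelayBuffer(), 0.0, 0.0)

    def test_never_returns_future_sample(self):
        buf = make_buffer(
            [SensorySample(time=t, v_x=t) for t in np.arange(0, 0.1, 0.005)]
        )
        assert sample_delayed(buf, 0.031, 0.0).v_x <= 0.031


@pytest.mark.parametrize(
    "law, args, expected",
    [
        (force_feedback, (1.2, 0.5), 0.6),
        (force_feedback, (1.2, 0.0), 0.0),
        (length_feedback, (1.0, 0.8, 1.0), 0.0),
        (length_feedback, (2.0, 1.1, 1.0), 0.2),
        (pd_stimulation, (2.0, 0.5, 0.0, 0.0, 0.2, "+"), 0.4),
        (pd_stimulation, (2.0, 0.5, 0.5, 0.0, 0.2, "+"), 0.0),
        (pd_stimulation, (2.0, 0.5, 0.2, 0.0, 0.2, "+"), 0.0),
        (pd_stimulation, (2.0, 0.5, 0.2, 0.0, 0.2, "-"), 0.0),
    ],
)
def test_feedback_laws_scalar_values(law, args, expected):
    assert law(*args) == pytest.approx(expected)


def test_force_feedback_linear_in_gain():
    assert force_feedback(2.4, 0.5) == pytest.approx(2 * force_feedback(1.2, 0.5))


def test_length_feedback_continuous_at_target():
    eps = 1e-9
    assert length_feedback(3.0, 1.0 + eps, 1.0) == pytest.approx(0.0, abs=1e-8)


def test_negative_gain_rejected():
    with pytest.raises(ValueError):
        force_feedback(-0.1, 0.5)
    with pytest.raises(ValueError):
        length_feedback(-1.0, 1.0, 1.0)


def test_simbicon_target_is_linear_in_d_and_v():
    p = ParameterVector.defaults().replace(theta_h0=0.1, c_d=0.5, c_v=0.2)
    assert simbicon_hip_target(p, 0.2, 1.5) == pytest.approx(0.1 + 0.1 + 0.3)


class TestComputeStimulations:
    def test_swing_with_zero_gains_gives_floor(self):
        rng = np.random.default_rng(0)
        buf = make_buffer([random_sample(rng, t) for t in np.arange(0, 0.1, 0.005)])
        zeros = {
            name: 0.0
            for name in (
                "G_HFL", "G_HAM_HFL", "G_GLU_sw", "G_HAM_sw", "G_TA_sw",
                "K_hip_sp", "D_hip_sp", "K_knee_sp", "D_knee_sp",
                "G_HAM_lsw", "G_GLU_lsw",
            )
        }
        zeros.update({f"u0_{m}_sw": 0.01 for m in MUSCLES})
        params = ParameterVector.defaults().replace(**zeros)
        u = compute_stimulations(LegPhase.SWING, buf, params, t=0.09)
        assert all(v == pytest.approx(U_MIN) for v in u.values())

    def test_stance_has_no_swing_circuit_contribution(self):
        """Zeroing every swing gain leaves stance outputs untouched."""
        rng = np.random.default_rng(1)
        buf = make_buffer([random_sample(rng, t) for t in np.arange(0, 0.1, 0.005)])
        base = ParameterVector.defaults()
        no_swing = base.replace(
            G_HFL=0.0, G_HAM_HFL=0.0, G_GLU_sw=0.0, G_HAM_sw=0.0, G_TA_sw=0.0
        )
        u_a = compute_stimulations(LegPhase.STANCE, buf, base, t=0.09)
        u_b = compute_stimulations(LegPhase.STANCE, buf, no_swing, t=0.09)
        assert u_a == u_b

    def test_ham_stretch_suppresses_hfl(self):
        """Stretched hamstring reduces swing-phase HFL drive (crossed L-)."""
        rng = np.random.default_rng(2)
        base_samples = [random_sample(rng, t) for t in np.arange(0, 0.1, 0.005)]
        stretched = []
        for s in base_samples:
            ml = dict(s.muscle_length)
            ml["HAM"] = 1.4
            ml["HFL"] = 1.3
            stretched.append(
                SensorySample(time=s.time, muscle_force=s.muscle_force,
                              muscle_length=ml, v_x=s.v_x, d=s.d)
            )
        slack = []
        for s in stretched:
            ml = dict(s.muscle_length)
            ml["HAM"] = 0.6
            slack.append(
                SensorySample(time=s.time, muscle_force=s.muscle_force,
                              muscle_length=ml, v_x=s.v_x, d=s.d)
            )
        params = ParameterVector.defaults().replace(
            G_HFL=2.0, l_HFL_tar=0.8, G_HAM_HFL=2.0, l_HAM_HFL_tar=0.9
        )
        u_stretched = compute_stimulations(
            LegPhase.SWING, make_buffer(stretched), params, t=0.09
        )
        u_slack = compute_stimulations(
            LegPhase.SWING, make_buffer(slack), params, t=0.09
        )
        assert u_stretched["HFL"] < u_slack["HFL"]

    @given(seed=st.integers(0, 2**16), phase=st.sampled_from(list(LegPhase)))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_outputs_bounded_for_random_traces(self, seed, phase):
        rng = np.random.default_rng(seed)
        buf = make_buffer([random_sample(rng, t) for t in np.arange(0, 0.1, 0.005)])
        unit = rng.uniform(0, 1, 56)
        from reflexgait.registry import denormalize

        params = ParameterVector(denormalize(unit))
        u = compute_stimulations(phase, buf, params, t=0.09)
        assert set(u) == set(MUSCLES)
        for v in u.values():
            assert U_MIN <= v <= 1.0

    def test_pure_function_of_inputs(self):
        rng = np.random.default_rng(3)
        samples = [random_sample(rng, t) for t in np.arange(0, 0.1, 0.005)]
        params = ParameterVector.defaults()
        u1 = compute_stimulations(LegPhase.LATE_STANCE, make_buffer(samples), params, 0.09)
        u2 = compute_stimulations(LegPhase.LATE_STANCE, make_buffer(samples), params, 0.09)
        assert u1 == u2

    def test_delay_shift_equivariance(self):
        """Shifting the input trace in time shifts outputs identically."""
        rng = np.random.default_rng(4)
        # exactly representable grid: unit steps, integer delays and shift
        shift = 10.0
        delays = {m: 4.0 if m in ("SOL", "TA", "GAS") else 2.0 for m in MUSCLES}
        samples = [random_sample(rng, float(t)) for t in range(40)]
        shifted = [
            SensorySample(
                time=s.time + shift, muscle_force=s.muscle_force,
                muscle_length=s.muscle_length, theta_t=s.theta_t,
                theta_h=s.theta_h, theta_k=s.theta_k,
                theta_t_dot=s.theta_t_dot, theta_h_dot=s.theta_h_dot,
                theta_k_dot=s.theta_k_dot, v_x=s.v_x, d=s.d,
            )
            for s in samples
        ]
        params = ParameterVector.defaults()
        u_a = compute_stimulations(
            LegPhase.STANCE, make_buffer(samples), params, 30.0, delays=delays
        )
        u_b = compute_stimulations(
            LegPhase.STANCE, make_buffer(shifted), params, 30.0 + shift, delays=delays
        )
        for m in MUSCLES:
            assert u_a[m] == pytest.approx(u_b[m])


class TestUpdatePhase:
    params = ParameterVector.defaults()

    def test_contact_gives_stance(self):
        phase, fell = update_phase(True, None, 0.1, self.params)
        assert phase is LegPhase.STANCE and not fell

    def test_contact_lost_gives_swing(self):
        phase, _ = update_phase(False, LegPhase.STANCE, 0.0, self.params)
        assert phase is LegPhase.SWING

    def test_torso_contact_raises_fall_flag(self):
        _, fell = update_phase(True, LegPhase.STANCE, 0.2, self.params, torso_contact=True)
        assert fell

    def test_subphase_thresholds(self):
        late, _ = update_phase(True, None, 0.95, self.params)
        assert late is LegPhase.LATE_STANCE
        prep, _ = update_phase(False, None, 0.95, self.params)
        assert prep is LegPhase.STANCE_PREPARATION
        late_sw, _ = update_phase(False, None, 0.7, self.params)
        assert late_sw is LegPhase.LATE_SWING
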