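"""Unit tests of the rotating-frame Bloch integrator and pulse primitives."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rexsim import (
    GAMMA_PROTON,
    FieldOffsets,
    PhysicsConstants,
    RelaxationParams,
    SimConfig,
    StimulusSpec,
    ahp_excite,
    effective_field,
    hard_rotation,
    rk4_integrate,
)

TWO_PI = 2.0 * math.pi


def rotation_oracle(state, w, duration):
    """Closed-form solution of dM/dt = M x w for constant w: a rotation by
    -|w|*duration about the unit field direction (scipy rotation matrix)."""
    w = np.asarray(w, dtype=float)
    return Rotation.from_rotvec(-w * duration).apply(state)


class TestEffectiveField:
    def test_pure_lock_field(self):
        w = effective_field(0.123, 50.0, 0.0, StimulusSpec.off(), FieldOffsets())
        assert w == pytest.approx([TWO_PI * 50.0, 0.0, 0.0])

    def test_stimulus_peak_z_component(self):
        # 50 nT stimulus peaks at gamma*B = 13.376 rad/s (2.129 Hz)
        stim = StimulusSpec(amplitude=50e-9, f_stim=50.0, phi=math.pi / 2)
        w = effective_field(0.0, 0.0, 0.0, stim, FieldOffsets())
        assert w[2] == pytest.approx(GAMMA_PROTON * 50e-9)
        assert w[2] == pytest.approx(13.3761, abs=1e-4)
        assert w[2] / TWO_PI == pytest.approx(2.1289, abs=1e-4)

    def test_static_offresonance_constant(self):
        offs = FieldOffsets(df0_static=26.6)
        t = np.linspace(0.0, 0.1, 7)
        w = effective_field(t, 50.0, 0.0, StimulusSpec.off(), offs)
        assert w.shape == (7, 3)
        assert np.allclose(w[:, 2], TWO_PI * 26.6)

    def test_b1_scale_scales_transverse(self):
        w = effective_field(0.0, 50.0, math.pi / 3, StimulusSpec.off(), FieldOffsets(b1_scale=0.9))
        assert np.hypot(w[0], w[1]) == pytest.approx(TWO_PI * 45.0)

    def test_negative_lock_amp_rejected(self):
        with pytest.raises(ValueError):
            effective_field(0.0, -1.0, 0.0, StimulusSpec.off(), FieldOffsets())


class TestRk4:
    def test_matches_rodrigues_for_constant_field(self, relax_off, cfg, rng):
        for _ in range(5):
            w = rng.normal(scale=300.0, size=3)
            m0 = rng.normal(size=3)
            m0 /= np.linalg.norm(m0)
            dur = rng.uniform(0.01, 0.08)
            m = rk4_integrate(m0, lambda t, w=w: w, dur, relax_off, cfg)
            assert np.linalg.norm(m - rotation_oracle(m0, w, dur)) < 1e-8

    def test_zero_field_identity(self, relax_off, cfg):
        m = rk4_integrate([0.3, -0.4, 0.5], lambda t: np.zeros(3), 0.1, relax_off, cfg)
        assert m == pytest.approx([0.3, -0.4, 0.5])

    def test_lock_axis_relaxation_is_exponential(self, cfg):
        relax = RelaxationParams(t1rho=0.1, t2rho=0.05)
        dur = 0.05
        m = rk4_integrate([1.0, 0.0, 0.0], lambda t: np.array([200.0, 0.0, 0.0]), dur, relax, cfg)
        assert m[0] == pytest.approx(math.exp(-dur / relax.t1rho), abs=1e-6)
        assert abs(m[1]) < 1e-9 and abs(m[2]) < 1e-9

    def test_perpendicular_relaxation_rate(self, cfg):
        # magnetization along z, lock field along x: decay at 1/t2rho while
        # precessing in the y-z plane
        relax = RelaxationParams(t1rho=0.1, t2rho=0.05)
        dur = 0.04
        m = rk4_integrate([0.0, 0.0, 1.0], lambda t: np.array([500.0, 0.0, 0.0]), dur, relax, cfg)
        assert np.linalg.norm(m) == pytest.approx(math.exp(-dur / relax.t2rho), abs=1e-6)

    def test_norm_conserved_over_piecewise_timeline(self, relax_off, cfg):
        # 250 ms spin-lock timeline with phase inversions, stimulus on
        stim = StimulusSpec(50e-9, 50.0, 0.4)
        m = hard_rotation([0.0, 0.0, 1.0], math.pi / 2, math.pi / 2)
        t0 = 0.0
        for phase, dur in ((0.0, 0.0625), (math.pi, 0.125), (0.0, 0.0625)):
            m = rk4_integrate(
                m,
                lambda t, p=phase: effective_field(t, 50.0, p, stim, FieldOffsets()),
                dur,
                relax_off,
                cfg,
                t0=t0,
            )
            m = hard_rotation(m, math.pi, 0.0)
            t0 += dur
        assert abs(np.linalg.norm(m) - 1.0) < 1e-6

    def test_fourth_order_convergence(self, relax_off):
        w = np.array([300.0, 200.0, 400.0])
        m0 = np.array([0.0, 0.0, 1.0])
        dur = 0.05
        ref = rotation_oracle(m0, w, dur)
        errs = []
        for dt in (2e-3, 1e-3):
            m = rk4_integrate(m0, lambda t: w, dur, relax_off, SimConfig(dt=dt))
            errs.append(np.linalg.norm(m - ref))
        assert errs[0] / errs[1] >= 8.0

    def test_single_step_fallback_when_dt_exceeds_duration(self, relax_off):
        cfg = SimConfig(dt=1.0)
        w = np.array([10.0, 0.0, 0.0])
        m = rk4_integrate([0.0, 0.0, 1.0], lambda t: w, 1e-3, relax_off, cfg)
        # one RK4 step of a small rotation is still accurate
        assert np.linalg.norm(m - rotation_oracle([0, 0, 1], w, 1e-3)) < 1e-8

    def test_nonfinite_state_rejected(self, relax_off, cfg):
        with pytest.raises(FloatingPointError):
            rk4_integrate([math.nan, 0.0, 0.0], lambda t: np.zeros(3), 0.01, relax_off, cfg)


class TestHardRotation:
    @pytest.mark.parametrize(
        "state,flip,axis_phase,expected",
        [
            ((0, 0, 1), math.pi / 2, math.pi / 2, (1, 0, 0)),
            ((0, 1, 0), math.pi, math.pi / 2, (0, 1, 0)),
            ((1, 0, 0), math.pi, math.pi / 2, (-1, 0, 0)),
        ],
    )
    def test_definitional_examples(self, state, flip, axis_phase, expected):
        assert hard_rotation(state, flip, axis_phase) == pytest.approx(expected, abs=1e-12)

    @given(
        flip=st.floats(-2 * math.pi, 2 * math.pi),
        axis_phase=st.floats(0.0, 2 * math.pi),
        mx=st.floats(-1, 1),
        my=st.floats(-1, 1),
        mz=st.floats(-1, 1),
    )
    def test_matches_rotation_matrix(self, flip, axis_phase, mx, my, mz):
        state = np.array([mx, my, mz])
        axis = np.array([math.cos(axis_phase), math.sin(axis_phase), 0.0])
        expected = Rotation.from_rotvec(flip * axis).apply(state)
        assert np.allclose(hard_rotation(state, flip, axis_phase), expected, atol=1e-12)


class TestAhp:
    @staticmethod
    def angle_to_x_deg(m):
        return math.degrees(math.acos(np.clip(m[0] / np.linalg.norm(m), -1.0, 1.0)))

    def test_ideal_mode_is_hard_90(self):
        assert ahp_excite([0.0, 0.0, 1.0], "ideal") == pytest.approx([1, 0, 0], abs=1e-12)

    def test_shaped_lands_near_x_axis(self):
        m = ahp_excite([0.0, 0.0, 1.0], "shaped")
        assert self.angle_to_x_deg(m) < 2.0

    def test_shaped_beats_scaled_hard_pulse_at_low_b1(self):
        # with 10% B1 droop the adiabatic passage still tracks the effective
        # field, while a hard pulse underrotates by 9 degrees
        offs = FieldOffsets(b1_scale=0.9)
        m_ahp = ahp_excite([0.0, 0.0, 1.0], "shaped", offs)
        m_hard = hard_rotation([0.0, 0.0, 1.0], 0.9 * math.pi / 2, math.pi / 2)
        assert self.angle_to_x_deg(m_ahp) < self.angle_to_x_deg(m_hard)

    def test_zero_b1_warns(self):
        with pytest.warns(RuntimeWarning):
            ahp_excite([0.0, 0.0, 1.0], "shaped", FieldOffsets(b1_scale=0.0))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            ahp_excite([0.0, 0.0, 1.0], "linear")


class TestParamValidation:
    def test_gamma_bar_consistency(self):
        c = PhysicsConstants()
        assert c.gamma_bar == pytest.approx(c.gamma / TWO_PI, rel=1e-15)

    def test_relaxation_ordering_enforced(self):
        with pytest.raises(ValueError):
            RelaxationParams(t1rho=0.05, t2rho=0.1)
        with pytest.raises(ValueError):
            RelaxationParams(t1rho=-1.0)

    def test_disabled_relaxation_skips_validation(self):
        assert not RelaxationParams.disabled().enabled

    def test_negative_b1_rejected(self):
        with pytest.raises(ValueError):
            FieldOffsets(b1_scale=-0.1)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(dt=0.0)
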