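"""Rotating-frame Bloch dynamics for spin-lock / rotary-excitation simulation.

The magnetization is tracked in the frame rotating at the RF carrier
frequency, as a dimensionless vector ``(mx, my, mz)`` normalized to the
thermal equilibrium magnetization ``M0 = 1``.  The effective field seen by
the spins is the sum of

* the spin-lock RF field: a constant transverse component of angular
  frequency ``2*pi*f_SL*b1_scale`` along the lock axis,
* a static off-resonance term ``2*pi*df0_static`` along z, and
* the oscillating stimulus ``gamma * dB0_stim * sin(2*pi*f_stim*t + phi)``
  along z (the ultra-weak field a REX experiment detects).

The equation of motion is ``dM/dt = M x omega_eff(t) - R(M)``, integrated
with a fixed-step 4th-order Runge-Kutta scheme.  ``R`` is the rotating-frame
relaxation operator: the component of ``M`` along the instantaneous
effective-field (lock) axis decays with ``T1rho``, the perpendicular
components with ``T2rho``.  No recovery term toward ``M0`` is applied during
preparation; at the <= 250 ms durations considered here longitudinal
recovery is negligible and the final signal is normalized to ``M0 = 1``.

Hard RF pulses (excitation and refocusing) are applied as instantaneous
rotations; the absolute time used by the stimulus phase does not advance
across them, since a real refocusing pulse is far shorter than one stimulus
period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "HZ_PER_PPM_3T",
    "PhysicsConstants",
    "RelaxationParams",
    "FieldOffsets",
    "SimConfig",
    "StimulusSpec",
    "effective_field",
    "rk4_integrate",
    "hard_rotation",
    "ahp_excite",
]

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.675221874e8

#: 1 ppm static off-resonance at 3 T, in Hz (convenience constant)
HZ_PER_PPM_3T = 127.7

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class PhysicsConstants:
    """Physical constants of the simulation (proton gyromagnetic ratio)."""

    gamma: float = GAMMA_PROTON  # rad s^-1 T^-1

    @property
    def gamma_bar(self) -> float:
        """gamma / (2*pi) in Hz/T."""
        return self.gamma / _TWO_PI


@dataclass(frozen=True)
class RelaxationParams:
    """Rotating-frame relaxation constants.

    Parameters
    ----------
    t1rho : float
        Decay time (s) of the magnetization component along the
        instantaneous lock axis.
    t2rho : float
        Decay time (s) of the components perpendicular to the lock axis.
        Physically ``t2rho <= t1rho``.
    enabled : bool
        If False, the dynamics are purely rotational (norm conserving).
    """

    t1rho: float = 0.100
    t2rho: float = 0.080
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled:
            if self.t1rho <= 0.0 or self.t2rho <= 0.0:
                raise ValueError("relaxation times must be positive")
            if self.t2rho > self.t1rho:
                raise ValueError("t2rho must not exceed t1rho")

    @staticmethod
    def disabled() -> "RelaxationParams":
        return RelaxationParams(enabled=False)


@dataclass(frozen=True)
class FieldOffsets:
    """Static field imperfections.

    ``df0_static`` is the static off-resonance in Hz
    (``delta_omega0 = 2*pi*df0_static``); ``b1_scale`` is the ratio of the
    actual to the nominal RF amplitude (1.0 = nominal).
    """

    df0_static: float = 0.0  # Hz
    b1_scale: float = 1.0  # dimensionless

    def __post_init__(self) -> None:
        if self.b1_scale < 0.0:
            raise ValueError("b1_scale must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Numerical integration settings.

    ``dt`` is the fixed RK4 step (default 20 us, >= 1000 steps per stimulus
    period at 50 Hz).  ``max_step_error_tol`` is the relative change in
    A_REX allowed when ``dt`` is halved (used by the convergence self-test).
    """

    dt: float = 2e-5  # s
    max_step_error_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """The oscillating field to be detected.

    ``amplitude`` is dB0_stim in Tesla (nT scale), ``f_stim`` the oscillation
    frequency in Hz and ``phi`` the phase of the oscillation relative to the
    start of the first spin-lock segment.  ``on=False`` switches the stimulus
    term off entirely (control scans).
    """

    amplitude: float = 50e-9  # T
    f_stim: float = 50.0  # Hz
    phi: float = 0.0  # rad
    on: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0.0:
            raise ValueError("stimulus amplitude must be >= 0")

    @staticmethod
    def off() -> "StimulusSpec":
        return StimulusSpec(on=False)

    def with_phi(self, phi: float) -> "StimulusSpec":
        return StimulusSpec(self.amplitude, self.f_stim, phi, self.on)


def effective_field(
    t,
    lock_amp: float,
    lock_phase: float,
    stimulus: StimulusSpec,
    offsets: FieldOffsets,
    consts: PhysicsConstants = PhysicsConstants(),
) -> np.ndarray:
    """Rotating-frame effective field (rad/s) at time(s) ``t``.

    ``lock_amp`` is the nominal spin-lock amplitude f_SL in Hz (scaled by
    ``offsets.b1_scale``); ``lock_phase`` sets the transverse lock axis.
    ``t`` is absolute time referenced to the start of the first spin-lock
    segment, so the stimulus phase evolves continuously across segments and
    instantaneous pulses.  Accepts scalar or array ``t``; returns shape
    ``t.shape + (3,)``.
    """
    if lock_amp < 0.0:
        raise ValueError("lock_amp must be >= 0")
    t = np.asarray(t, dtype=float)
    w1 = _TWO_PI * lock_amp * offsets.b1_scale
    wz0 = _TWO_PI * offsets.df0_static
    out = np.empty(t.shape + (3,), dtype=float)
    out[..., 0] = w1 * math.cos(lock_phase)
    out[..., 1] = w1 * math.sin(lock_phase)
    if stimulus.on and stimulus.amplitude > 0.0:
        out[..., 2] = wz0 + consts.gamma * stimulus.amplitude * np.sin(
            _TWO_PI * stimulus.f_stim * t + stimulus.phi
        )
    else:
        out[..., 2] = wz0
    return out


def _bloch_deriv(m: np.ndarray, w: np.ndarray, relax: RelaxationParams) -> np.ndarray:
    """dM/dt = M x w - relaxation, vectorized over leading axes."""
    mx, my, mz = m[..., 0], m[..., 1], m[..., 2]
    wx, wy, wz = w[..., 0], w[..., 1], w[..., 2]
    d = np.empty(np.broadcast_shapes(m.shape, w.shape), dtype=float)
    d[..., 0] = my * wz - mz * wy
    d[..., 1] = mz * wx - mx * wz
    d[..., 2] = mx * wy - my * wx
    if relax.enabled:
        r1 = 1.0 / relax.t1rho
        r2 = 1.0 / relax.t2rho
        w2 = wx * wx + wy * wy + wz * wz
        # projection of M on the lock axis; with zero field there is no lock
        # axis and the decay is uniformly transverse-like (T2rho)
        proj = (mx * wx + my * wy + mz * wz) / np.where(w2 > 0.0, w2, 1.0)
        proj = np.where(w2 > 0.0, proj, 0.0)
        dr = r1 - r2
        d[..., 0] -= r2 * mx + dr * proj * wx
        d[..., 1] -= r2 * my + dr * proj * wy
        d[..., 2] -= r2 * mz + dr * proj * wz
    return d


def _rk4_steps(m, t0, h, n_steps, omega, relax):
    """Advance a batch of magnetization vectors by ``n_steps`` RK4 steps.

    ``m``: (..., 3); ``t0``, ``h``: per-spin start times and step sizes
    (broadcastable to the batch shape); ``omega(t) -> (..., 3)``.
    """
    hh = np.asarray(h, dtype=float)[..., None]
    for k in range(n_steps):
        t = t0 + k * h
        w1 = omega(t)
        wm = omega(t + 0.5 * h)
        w4 = omega(t + h)
        k1 = _bloch_deriv(m, w1, relax)
        k2 = _bloch_deriv(m + 0.5 * hh * k1, wm, relax)
        k3 = _bloch_deriv(m + 0.5 * hh * k2, wm, relax)
        k4 = _bloch_deriv(m + hh * k3, w4, relax)
        m = m + (hh / 6.0) * (k1 + 2.0 * (k2 + k3) + k4)
    return m


def rk4_integrate(
    state,
    field_fn,
    duration: float,
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """Integrate ``dM/dt = M x omega(t) - R(M)`` over ``duration`` seconds.

    ``field_fn(t)`` must return the effective field (rad/s) at absolute time
    ``t`` as an array of shape ``(3,)`` (or broadcastable to the state
    shape).  ``state`` may be a single vector ``(3,)`` or a batch
    ``(..., 3)``.  If ``cfg.dt`` exceeds ``duration`` a single step of size
    ``duration`` is taken.
    """
    if duration < 0.0:
        raise ValueError("duration must be >= 0")
    m = np.array(state, dtype=float)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("non-finite magnetization state")
    if duration == 0.0:
        return m
    relax = relax if relax is not None else RelaxationParams.disabled()
    cfg = cfg if cfg is not None else SimConfig()
    n = max(1, int(math.ceil(duration / cfg.dt - 1e-12)))
    h = duration / n

    def omega(t):
        return np.asarray(field_fn(float(np.asarray(t).reshape(-1)[0])), dtype=float)

    m = _rk4_steps(m, np.asarray(t0, dtype=float), np.asarray(h), n, omega, relax)
    if not np.all(np.isfinite(m)):
        raise FloatingPointError("integration produced non-finite state")
    return m


def hard_rotation(state, flip: float, axis_phase: float) -> np.ndarray:
    """Instantaneous rotation by ``flip`` about the transverse axis
    ``(cos(axis_phase), sin(axis_phase), 0)`` (Rodrigues formula).

    Zero elapsed time: the stimulus phase clock is unaffected.
    """
    m = np.asarray(state, dtype=float)
    ax, ay = math.cos(axis_phase), math.sin(axis_phase)
    c, s = math.cos(flip), math.sin(flip)
    mx, my, mz = m[..., 0], m[..., 1], m[..., 2]
    dot = mx * ax + my * ay
    out = np.empty_like(m)
    out[..., 0] = mx * c + ay * mz * s + ax * dot * (1.0 - c)
    out[..., 1] = my * c - ax * mz * s + ay * dot * (1.0 - c)
    out[..., 2] = mz * c + (ax * my - ay * mx) * s
    return out


# Shaped adiabatic-half-passage settings: hyperbolic-secant amplitude with a
# tanh frequency sweep over 3 ms.  The peak RF amplitude and sweep width are
# chosen so the passage stays adiabatic at nominal B1 (final angle to x' well
# below 2 degrees) while remaining robust to moderate B1 reduction.
AHP_DURATION = 3e-3  # s
AHP_BETA = 6.0  # truncation factor of the sech/tanh shapes
AHP_PEAK_F1_HZ = 5000.0  # peak RF amplitude (gamma*B1max/2pi)
AHP_SWEEP_F_HZ = 2000.0  # frequency-sweep half-width


def ahp_excite(
    state,
    mode: str = "ideal",
    offsets: FieldOffsets = FieldOffsets(),
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
) -> np.ndarray:
    """Adiabatic-half-passage excitation: land the magnetization on x'.

    ``mode="ideal"`` applies an instantaneous 90 degree rotation about y'
    (equivalent to a perfect AHP).  ``mode="shaped"`` integrates a 3 ms
    hyperbolic-secant RF amplitude along x' with a tanh frequency sweep from
    ``+AHP_SWEEP_F_HZ`` down to zero; the magnetization follows the effective
    field from +z to x'.  Relaxation is applied during the shaped pulse when
    ``relax`` is enabled; the ideal mode is relaxation free.
    """
    if mode == "ideal":
        return hard_rotation(state, math.pi / 2.0, math.pi / 2.0)
    if mode != "shaped":
        raise ValueError(f"unknown AHP mode {mode!r}")
    if offsets.b1_scale == 0.0:
        warnings.warn(
            "AHP with b1_scale=0: no RF field, adiabatic passage fails",
            RuntimeWarning,
            stacklevel=2,
        )
    w1_peak = _TWO_PI * AHP_PEAK_F1_HZ * offsets.b1_scale
    sweep = _TWO_PI * AHP_SWEEP_F_HZ
    wz_off = _TWO_PI * offsets.df0_static

    def field(t):
        tau = t / AHP_DURATION - 1.0  # in [-1, 0]
        w1 = w1_peak / math.cosh(AHP_BETA * tau)
        dw = -sweep * math.tanh(AHP_BETA * tau) + wz_off
        return np.array([w1, 0.0, dw])

    return rk4_integrate(state, field, AHP_DURATION, relax, cfg)
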