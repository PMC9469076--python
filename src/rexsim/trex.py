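"""tREX gradient-waveform design.

Instead of dedicated field-generating hardware, the scanner's own gradient
system can transmit the oscillating stimulus: a slice at offcenter distance
``dz`` sees the field ``G_z(t) * dz``, so the waveform

    G_z(t) = dB0_stim / dz * sin(2*pi*f_stim*t + phi)

realizes a target oscillation amplitude ``dB0_stim`` in that slice.  The
achievable amplitude is bounded below by the quantization floor of the
gradient amplifiers (about 0.1 nT/mm on a standard clinical system).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bloch import StimulusSpec

__all__ = [
    "GRADIENT_FLOOR_T_PER_M",
    "TrexWaveform",
    "gz_waveform",
    "feasibility_check",
    "write_waveform_csv",
    "read_waveform_csv",
]

#: default per-axis minimum usable gradient amplitude: 0.1 nT/mm in T/m
GRADIENT_FLOOR_T_PER_M = 1e-7


@dataclass(frozen=True)
class TrexWaveform:
    """A sampled sinusoidal gradient waveform (SI units)."""

    dz: float  # offcenter distance, m
    stimulus: StimulusSpec
    times: np.ndarray  # s
    gradient: np.ndarray  # T/m
    raster: float  # s

    @property
    def peak_gradient(self) -> float:
        """amplitude / dz, in T/m."""
        return self.stimulus.amplitude / abs(self.dz)

    def field_at(self, z: float) -> np.ndarray:
        """Field (T) seen at position ``z`` (m), linear in z."""
        return self.gradient * z


def gz_waveform(
    stimulus: StimulusSpec,
    dz: float,
    duration: float,
    raster: float = 1e-5,
) -> TrexWaveform:
    """Sample the gradient waveform realizing ``stimulus`` at offcenter ``dz``.

    ``raster`` is the gradient raster time (default 10 us).  Raises for
    ``dz = 0``: no oscillation can be transmitted to an isocenter slice.
    """
    if dz == 0.0:
        raise ValueError("dz must be nonzero: no field can be transmitted in an isocenter slice")
    if duration <= 0.0 or raster <= 0.0:
        raise ValueError("duration and raster must be positive")
    n = int(round(duration / raster))
    times = np.arange(n + 1) * raster
    grad = (stimulus.amplitude / dz) * np.sin(
        2.0 * math.pi * stimulus.f_stim * times + stimulus.phi
    )
    return TrexWaveform(dz, stimulus, times, grad, raster)


def feasibility_check(
    stimulus: StimulusSpec,
    dz: float,
    floor: float = GRADIENT_FLOOR_T_PER_M,
) -> str:
    """Classify a target stimulus against the gradient quantization floor.

    Returns ``"feasible"`` when the peak gradient is at least 10x the
    floor, ``"marginal"`` when it only reaches the floor (oscillation
    detectable but noisy), ``"infeasible"`` below it.
    """
    if floor <= 0.0:
        raise ValueError("floor must be positive")
    if dz == 0.0:
        raise ValueError("dz must be nonzero")
    peak = stimulus.amplitude / abs(dz)
    if peak >= 10.0 * floor:
        return "feasible"
    if peak >= floor:
        return "marginal"
    return "infeasible"


def write_waveform_csv(wf: TrexWaveform, path) -> None:
    """Write the waveform as CSV with columns ``time_s, g_T_per_m``."""
    pd.DataFrame({"time_s": wf.times, "g_T_per_m": wf.gradient}).to_csv(path, index=False)


def read_waveform_csv(path, dz: float, stimulus: StimulusSpec) -> TrexWaveform:
    """Read a waveform written by :func:`write_waveform_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    times = df["time_s"].to_numpy(dtype=float)
    grad = df["g_T_per_m"].to_numpy(dtype=float)
    raster = float(times[1] - times[0]) if times.size > 1 else 0.0
    return TrexWaveform(dz, stimulus, times, grad, raster)
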