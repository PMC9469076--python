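"""Parameter sweeps of the rotary-excitation amplitude.

Every sweep evaluates, per grid point, the amplitude A_REX as the sample
standard deviation of the post-crusher signal over ``n_phases`` stimulus
phases uniformly spaced on [0, 2*pi).  All sweeps are deterministic: for
fixed grids, step size and phase count the results are bitwise
reproducible.

The Bloch integrations are batched: many (t_SL, phase, ...) combinations
are advanced in lockstep through the vectorized RK4 engine.  Grid points
with very different spin-lock durations are chunked by duration so short
preparations are not integrated with needlessly many steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bloch import RelaxationParams, SimConfig
from .prep import MODULE_NAMES, run_preparation_batch
from .rexsignal import uniform_phases

__all__ = [
    "OPTIMAL_TSL_50HZ",
    "SweepResult",
    "resonance_tsl_curve",
    "sweep_tsl_fsl",
    "sweep_resonant_fstim",
    "sweep_offresonance",
    "half_amplitude_offset",
    "sweep_stim_amplitude",
    "linearity_r2",
    "write_sweep_csv",
    "read_sweep_csv",
]

#: optimal total spin-lock durations (s) per module for f_stim = 50 Hz,
#: from the maxima-prediction law (k = 8, 7, 4, 2 respectively)
OPTIMAL_TSL_50HZ = {"S-SL": 0.0775, "RE-SL": 0.070, "C-SL": 0.080, "B-SL": 0.080}

_DEFAULT_CHUNK = 40


@dataclass
class SweepResult:
    """An amplitude grid over one or two swept axes.

    ``axes`` maps axis name to its grid values (insertion order = array
    axis order); ``a_rex`` has shape ``tuple(len(v) for v in axes)``.
    ``metadata`` records the fixed parameters of the sweep.
    """

    axes: dict
    a_rex: np.ndarray
    metadata: dict = field(default_factory=dict)

    def axis(self, name: str) -> np.ndarray:
        return self.axes[name]


def _amp_std(signals: np.ndarray) -> np.ndarray:
    """Sample standard deviation over the trailing (phase) axis."""
    return np.std(signals, axis=-1, ddof=1)


def _chunks(n: int, size: int):
    for i in range(0, n, size):
        yield slice(i, min(i + size, n))


def _meta(name, relax, cfg, n_phases, **fixed):
    md = {
        "module": name,
        "dt_s": cfg.dt,
        "n_phases": n_phases,
        "relaxation_enabled": relax.enabled,
    }
    if relax.enabled:
        md["t1rho_s"] = relax.t1rho
        md["t2rho_s"] = relax.t2rho
    md.update(fixed)
    return md


def resonance_tsl_curve(
    name: str,
    t_grid,
    f_stim: float = 50.0,
    amplitude: float = 50e-9,
    n_phases: int = 10,
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
    chunk: int = _DEFAULT_CHUNK,
) -> SweepResult:
    """A_REX versus t_SL on resonance (f_SL = f_stim)."""
    relax = relax if relax is not None else RelaxationParams()
    cfg = cfg if cfg is not None else SimConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    phases = uniform_phases(n_phases)
    a = np.empty(t_grid.size)
    for sl in _chunks(t_grid.size, chunk):
        t_b = t_grid[sl][:, None]
        sig = run_preparation_batch(
            name, t_b, phases[None, :], f_stim=f_stim, amplitude=amplitude,
            relax=relax, cfg=cfg,
        )
        a[sl] = _amp_std(sig)
    return SweepResult(
        {"t_sl_s": t_grid},
        a,
        _meta(name, relax, cfg, n_phases, f_stim_hz=f_stim, f_sl_hz=f_stim,
              stim_amplitude_t=amplitude),
    )


def sweep_tsl_fsl(
    name: str,
    t_grid,
    f_grid,
    f_stim: float = 50.0,
    amplitude: float = 50e-9,
    n_phases: int = 10,
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
    chunk: int = _DEFAULT_CHUNK,
) -> SweepResult:
    """A_REX heatmap over (t_SL, f_SL) at fixed stimulus frequency."""
    relax = relax if relax is not None else RelaxationParams()
    cfg = cfg if cfg is not None else SimConfig()
    t_grid = np.asarray(t_grid, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if t_grid.size == 0 or f_grid.size == 0:
        raise ValueError("grids must be non-empty")
    a = np.empty((t_grid.size, f_grid.size))
    for sl in _chunks(t_grid.size, chunk):
        t_b = t_grid[sl][:, None, None]
        sig = run_preparation_batch(
            name,
            t_b,
            uniform_phases(n_phases)[None, None, :],
            f_sl=f_grid[None, :, None],
            f_stim=f_stim,
            amplitude=amplitude,
            relax=relax,
            cfg=cfg,
        )
        a[sl] = _amp_std(sig)
    return SweepResult(
        {"t_sl_s": t_grid, "f_sl_hz": f_grid},
        a,
        _meta(name, relax, cfg, n_phases, f_stim_hz=f_stim, stim_amplitude_t=amplitude),
    )


def sweep_resonant_fstim(
    name: str,
    f_stim_grid,
    t_grid,
    amplitude: float = 50e-9,
    n_phases: int = 10,
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
    chunk: int = _DEFAULT_CHUNK,
) -> SweepResult:
    """A_REX over (f_stim, t_SL) with f_SL slaved to f_stim (resonance)."""
    relax = relax if relax is not None else RelaxationParams()
    cfg = cfg if cfg is not None else SimConfig()
    f_stim_grid = np.asarray(f_stim_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or f_stim_grid.size == 0:
        raise ValueError("grids must be non-empty")
    a = np.empty((f_stim_grid.size, t_grid.size))
    for sl in _chunks(t_grid.size, chunk):
        t_b = t_grid[sl][None, :, None]
        sig = run_preparation_batch(
            name,
            t_b,
            uniform_phases(n_phases)[None, None, :],
            f_stim=f_stim_grid[:, None, None],
            amplitude=amplitude,
            relax=relax,
            cfg=cfg,
        )
        a[:, sl] = _amp_std(sig)
    return SweepResult(
        {"f_stim_hz": f_stim_grid, "t_sl_s": t_grid},
        a,
        _meta(name, relax, cfg, n_phases, stim_amplitude_t=amplitude,
              resonance="f_sl = f_stim"),
    )


def default_offresonance_grid(
    span_ppm: float = 1.0, step_ppm: float = 0.004, hz_per_ppm: float = 127.7
) -> np.ndarray:
    """Symmetric off-resonance grid in Hz (default +-1 ppm at 3 T in
    0.004 ppm steps)."""
    n = int(round(span_ppm / step_ppm))
    return np.arange(-n, n + 1) * step_ppm * hz_per_ppm


def sweep_offresonance(
    name: str,
    t_sl_opt: float | None = None,
    df0_grid=None,
    f_stim: float = 50.0,
    amplitude: float = 50e-9,
    n_phases: int = 10,
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
) -> SweepResult:
    """A_REX versus static off-resonance at the module's optimal t_SL."""
    relax = relax if relax is not None else RelaxationParams()
    cfg = cfg if cfg is not None else SimConfig()
    if t_sl_opt is None:
        t_sl_opt = OPTIMAL_TSL_50HZ[name]
    df0_grid = (
        default_offresonance_grid() if df0_grid is None else np.asarray(df0_grid, dtype=float)
    )
    sig = run_preparation_batch(
        name,
        t_sl_opt,
        uniform_phases(n_phases)[None, :],
        f_stim=f_stim,
        amplitude=amplitude,
        df0_static=df0_grid[:, None],
        relax=relax,
        cfg=cfg,
    )
    return SweepResult(
        {"df0_hz": df0_grid},
        _amp_std(sig),
        _meta(name, relax, cfg, n_phases, f_stim_hz=f_stim, f_sl_hz=f_stim,
              t_sl_s=t_sl_opt, stim_amplitude_t=amplitude),
    )


def half_amplitude_offset(df0_grid, a_rex) -> float:
    """|df0| (Hz) at which the curve first falls to half its value at
    df0 = 0, linearly interpolated and averaged over both sides."""
    df0 = np.asarray(df0_grid, dtype=float)
    a = np.asarray(a_rex, dtype=float)
    i0 = int(np.argmin(np.abs(df0)))
    half = 0.5 * a[i0]
    crossings = []
    for step in (1, -1):
        j = i0 + step
        found = None
        while 0 <= j < a.size:
            if a[j] < half:
                prev = j - step
                frac = (a[prev] - half) / (a[prev] - a[j])
                found = abs(df0[prev] + frac * (df0[j] - df0[prev]))
                break
            j += step
        if found is not None:
            crossings.append(found)
    if not crossings:
        raise ValueError("no half-amplitude crossing found within the swept range")
    return float(np.mean(crossings))


def sweep_stim_amplitude(
    name: str = "B-SL",
    amp_grid=None,
    t_sl_opt: float | None = None,
    f_stim: float = 50.0,
    n_phases: int = 10,
    relax: RelaxationParams | None = None,
    cfg: SimConfig | None = None,
) -> SweepResult:
    """A_REX versus stimulus amplitude (linearity of the detector)."""
    relax = relax if relax is not None else RelaxationParams()
    cfg = cfg if cfg is not None else SimConfig()
    if t_sl_opt is None:
        t_sl_opt = OPTIMAL_TSL_50HZ[name]
    amp_grid = (
        np.linspace(5e-9, 100e-9, 15) if amp_grid is None else np.asarray(amp_grid, dtype=float)
    )
    sig = run_preparation_batch(
        name,
        t_sl_opt,
        uniform_phases(n_phases)[None, :],
        f_stim=f_stim,
        amplitude=amp_grid[:, None],
        relax=relax,
        cfg=cfg,
    )
    return SweepResult(
        {"stim_amplitude_t": amp_grid},
        _amp_std(sig),
        _meta(name, relax, cfg, n_phases, f_stim_hz=f_stim, f_sl_hz=f_stim,
              t_sl_s=t_sl_opt),
    )


def linearity_r2(x, y) -> float:
    """R^2 of an ordinary least-squares line through (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("linearity check needs at least 3 points")
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def write_sweep_csv(result: SweepResult, path) -> None:
    """Write a sweep as long-format CSV (one row per grid point) plus a
    ``<path>.meta.txt`` sidecar with the sweep metadata as JSON."""
    names = list(result.axes)
    grids = np.meshgrid(*(result.axes[n] for n in names), indexing="ij")
    data = {n: g.ravel() for n, g in zip(names, grids)}
    data["a_rex"] = result.a_rex.ravel()
    # default float formatting is the shortest round-trippable repr
    pd.DataFrame(data).to_csv(path, index=False)
    with open(f"{path}.meta.txt", "w") as fh:
        # axis order is significant: keep insertion order, no key sorting
        json.dump(
            {"axes": {n: len(result.axes[n]) for n in names}, **result.metadata},
            fh,
            indent=2,
        )
        fh.write("\n")


def read_sweep_csv(path) -> SweepResult:
    """Read a sweep written by :func:`write_sweep_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    with open(f"{path}.meta.txt") as fh:
        meta = json.load(fh)
    axis_sizes = meta.pop("axes")
    names = list(axis_sizes)
    shape = tuple(axis_sizes[n] for n in names)
    axes = {}
    for i, n in enumerate(names):
        col = df[n].to_numpy(dtype=float).reshape(shape)
        sel = tuple(slice(None) if j == i else 0 for j in range(len(names)))
        axes[n] = col[sel]
    return SweepResult(axes, df["a_rex"].to_numpy(dtype=float).reshape(shape), meta)
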