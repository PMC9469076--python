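"""Synthetic image-series pipeline for pixel-wise amplitude mapping.

Generates 2D "slices" with spatially smooth off-resonance and B1+ maps,
simulates per-pixel phase-series stacks of REX-weighted signals (either by
running the full Bloch preparation per distinct field value, or by a fast
sinusoidal surrogate parameterized from the Bloch engine on a coarse field
lookup), and computes per-pixel amplitude and fit-parameter maps.

The images are ideal per-pixel signal maps: no k-space encoding, readout
blurring or motion is modeled, and the optional noise is additive Gaussian
on the magnitude images.  What passes here therefore validates the
preparation physics and the estimators, not the imaging chain of a real
scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .bloch import RelaxationParams, SimConfig
from .prep import MODULE_NAMES, run_preparation_batch
from .rexsignal import RexSeries, amplitude_std, fit_rex, uniform_phases

__all__ = [
    "PhantomScene",
    "RexImageStack",
    "AmplitudeMaps",
    "make_phantom",
    "simulate_stack",
    "amplitude_map",
    "spatial_cv",
]

_SQRT2 = math.sqrt(2.0)

#: cache quantization of the Bloch engine: off-resonance bin (Hz), B1 bin
_DF0_BIN_HZ = 0.5
_B1_BIN = 0.01


@dataclass(frozen=True)
class PhantomScene:
    """A synthetic 2D slice: mask plus smooth field and relaxation maps."""

    shape: tuple
    mask: np.ndarray  # bool
    df0_map: np.ndarray  # Hz
    b1_map: np.ndarray  # dimensionless
    t1rho_map: np.ndarray  # s
    t2rho_map: np.ndarray  # s
    seed: int
    fov_m: float = 0.15


@dataclass(frozen=True)
class RexImageStack:
    """A phase series of 2D REX-weighted images."""

    phases: np.ndarray  # rad, length N
    images: np.ndarray  # (N, H, W)
    s0_image: np.ndarray  # (H, W) reference
    mask: np.ndarray  # (H, W) bool
    noise_sigma: float
    seed: int
    metadata: dict = field(default_factory=dict)

    def pixel_series(self, i: int, j: int) -> RexSeries:
        return RexSeries(self.phases, self.images[:, i, j], float(self.s0_image[i, j]))


@dataclass(frozen=True)
class AmplitudeMaps:
    """Per-pixel estimator maps (NaN outside the mask / on fit failure)."""

    a_rex: np.ndarray
    method: str
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    phi0: np.ndarray | None = None
    m: np.ndarray | None = None
    r2: np.ndarray | None = None
    failed: np.ndarray | None = None  # bool, fit failures


def make_phantom(
    shape=(48, 48),
    inhomogeneity_profile: str = "uniform",
    seed: int = 0,
    fov_m: float = 0.15,
    gradient_hz_per_cm: float = 3.2,
    hotspot_peak_hz: float = 60.0,
    t1rho: float = 0.100,
    t2rho: float = 0.080,
) -> PhantomScene:
    """Build a deterministic synthetic slice.

    Profiles:

    * ``uniform``        constant maps (df0 = 0, b1 = 1),
    * ``linear_gradient`` off-resonance linear in x (``gradient_hz_per_cm``
      across the field of view) with a mild radial B1+ droop,
    * ``hotspot``        a localized Gaussian off-resonance bump (peak
      ``hotspot_peak_hz``, emulating e.g. air-tissue interfaces) on a
      smooth seeded background.
    """
    if min(shape) < 16:
        raise ValueError("shape must be at least 16x16")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rnorm = np.hypot((yy - cy) / cy, (xx - cx) / cx) / math.sqrt(2.0)
    mask = rnorm <= 0.9
    x_cm = (xx - cx) / (w - 1) * fov_m * 100.0  # cm from center
    rng = np.random.default_rng(seed)
    if inhomogeneity_profile == "uniform":
        df0 = np.zeros(shape)
        b1 = np.ones(shape)
    elif inhomogeneity_profile == "linear_gradient":
        df0 = gradient_hz_per_cm * x_cm
        b1 = 1.0 - 0.1 * rnorm**2
    elif inhomogeneity_profile == "hotspot":
        sy = cy + rng.uniform(-0.3, 0.3) * cy
        sx = cx + rng.uniform(-0.3, 0.3) * cx
        sigma = 0.12 * min(h, w)
        bump = hotspot_peak_hz * np.exp(-((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * sigma**2))
        background = 3.0 * np.sin(2 * math.pi * xx / w + rng.uniform(0, 2 * math.pi))
        df0 = bump + background
        b1 = 1.0 - 0.08 * rnorm**2
    else:
        raise ValueError(f"unknown inhomogeneity profile {inhomogeneity_profile!r}")
    return PhantomScene(
        shape=(h, w),
        mask=mask,
        df0_map=df0,
        b1_map=np.clip(b1, 0.7, 1.2),
        t1rho_map=np.full(shape, t1rho),
        t2rho_map=np.full(shape, t2rho),
        seed=seed,
        fov_m=fov_m,
    )


def _bloch_pixel_signals(scene, mask, name, t_sl, stimulus, phases, relax, cfg):
    """Per-pixel signals via the Bloch engine, cached on quantized
    (df0, b1) pairs."""
    df0_q = np.round(scene.df0_map[mask] / _DF0_BIN_HZ) * _DF0_BIN_HZ
    b1_q = np.round(scene.b1_map[mask] / _B1_BIN) * _B1_BIN
    pairs, inverse = np.unique(
        np.stack([df0_q, b1_q], axis=1), axis=0, return_inverse=True
    )
    sig = run_preparation_batch(
        name,
        t_sl,
        (phases[None, :] + stimulus.phi),
        f_stim=stimulus.f_stim,
        amplitude=stimulus.amplitude,
        stim_on=stimulus.on,
        df0_static=pairs[:, 0][:, None],
        b1_scale=pairs[:, 1][:, None],
        relax=relax,
        cfg=cfg,
    )
    return sig[inverse]  # (n_pixels, n_phases)


def _surrogate_pixel_signals(scene, mask, name, t_sl, stimulus, phases, relax, cfg):
    """Per-pixel signals from the sinusoidal model, with (a, b, phi0, m)
    interpolated from Bloch runs on a coarse (df0, b1) node grid."""
    df0 = scene.df0_map[mask]
    b1 = scene.b1_map[mask]
    df0_nodes = _node_grid(df0, step=5.0)
    b1_nodes = _node_grid(b1, step=0.05)
    fit_phases = uniform_phases(16)
    sig = run_preparation_batch(
        name,
        t_sl,
        (fit_phases + stimulus.phi)[None, None, :],
        f_stim=stimulus.f_stim,
        amplitude=stimulus.amplitude,
        stim_on=stimulus.on,
        df0_static=df0_nodes[:, None, None],
        b1_scale=b1_nodes[None, :, None],
        relax=relax,
        cfg=cfg,
    )
    params = np.empty(sig.shape[:2] + (4,))  # a*e^{i phi0} (re, im), b, m
    for i in range(sig.shape[0]):
        for j in range(sig.shape[1]):
            fit = fit_rex(RexSeries(fit_phases, sig[i, j]))
            if fit.converged:
                params[i, j] = (
                    fit.a * math.cos(fit.phi0),
                    fit.a * math.sin(fit.phi0),
                    fit.b,
                    fit.m,
                )
            else:  # stimulus off / degenerate: flat series
                params[i, j] = (0.0, 0.0, float(np.mean(sig[i, j])), 1.0)
    interp = RegularGridInterpolator(
        (df0_nodes, b1_nodes), params, bounds_error=False, fill_value=None
    )
    px = interp(np.stack([df0, b1], axis=1))
    a = np.hypot(px[:, 0], px[:, 1])
    phi0 = np.arctan2(px[:, 1], px[:, 0])
    b = px[:, 2]
    m = px[:, 3]
    return (
        a[:, None] * _SQRT2 * np.sin(phases[None, :] * m[:, None] + phi0[:, None])
        + b[:, None]
    )


def _node_grid(values: np.ndarray, step: float) -> np.ndarray:
    lo = math.floor(values.min() / step) * step
    hi = math.ceil(values.max() / step) * step
    if hi - lo < step:
        hi = lo + step
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n)


def simulate_stack(
    scene: PhantomScene,
    module_name: str,
    t_sl: float,
    stimulus,
    n_phases: int = 20,
    noise_sigma: float = 0.01,
    seed: int = 0,
    engine: str = "bloch",
    cfg: SimConfig | None = None,
) -> RexImageStack:
    """Simulate a REX-weighted phase-series stack for a scene.

    ``engine="bloch"`` runs the full preparation per distinct quantized
    (df0, b1) value; ``engine="surrogate"`` samples the sinusoidal signal
    model with parameters interpolated from a coarse Bloch lookup (fast for
    large scenes).  Additive Gaussian noise of ``noise_sigma`` (units of
    S0) is applied to each image, seeded and reproducible.  With the
    stimulus off, the stacks are oscillation free (noise only).
    """
    if module_name not in MODULE_NAMES:
        raise ValueError(f"unknown preparation module {module_name!r}")
    cfg = cfg if cfg is not None else SimConfig()
    relax = RelaxationParams(
        t1rho=float(np.median(scene.t1rho_map)),
        t2rho=float(np.median(scene.t2rho_map)),
    )
    phases = uniform_phases(n_phases)
    if engine == "bloch":
        px_signals = _bloch_pixel_signals(
            scene, scene.mask, module_name, t_sl, stimulus, phases, relax, cfg
        )
    elif engine == "surrogate":
        px_signals = _surrogate_pixel_signals(
            scene, scene.mask, module_name, t_sl, stimulus, phases, relax, cfg
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    h, w = scene.shape
    images = np.zeros((n_phases, h, w))
    images[:, scene.mask] = px_signals.T
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        images = images + noise_sigma * rng.standard_normal(images.shape)
    return RexImageStack(
        phases=phases,
        images=images,
        s0_image=np.ones((h, w)),
        mask=scene.mask.copy(),
        noise_sigma=noise_sigma,
        seed=seed,
        metadata={
            "module": module_name,
            "t_sl_s": t_sl,
            "engine": engine,
            "f_stim_hz": stimulus.f_stim,
            "stim_amplitude_t": stimulus.amplitude,
            "stim_on": stimulus.on,
        },
    )


def amplitude_map(stack: RexImageStack, method: str = "std") -> AmplitudeMaps:
    """Per-pixel A_REX map (``method="std"``) or full sinusoidal-fit maps
    (``method="fit"``).  Masked-out pixels are NaN; per-pixel fit failures
    are marked in ``failed`` and set NaN, never fatal."""
    h, w = stack.s0_image.shape
    norm = stack.images / stack.s0_image[None, :, :]
    if method == "std":
        if stack.phases.size < 2:
            raise ValueError("std method needs at least 2 phases")
        a_rex = np.std(norm, axis=0, ddof=1)
        a_rex[~stack.mask] = np.nan
        return AmplitudeMaps(a_rex=a_rex, method="std")
    if method != "fit":
        raise ValueError(f"unknown method {method!r}")
    if stack.phases.size < 5:
        raise ValueError("fit method needs at least 5 phases")
    maps = {k: np.full((h, w), np.nan) for k in ("a_rex", "a", "b", "phi0", "m", "r2")}
    failed = np.zeros((h, w), dtype=bool)
    for i, j in zip(*np.nonzero(stack.mask)):
        fit = fit_rex(RexSeries(stack.phases, norm[:, i, j]))
        if not fit.converged:
            failed[i, j] = True
            continue
        maps["a_rex"][i, j] = fit.a_rex
        maps["a"][i, j] = fit.a
        maps["b"][i, j] = fit.b
        maps["phi0"][i, j] = fit.phi0
        maps["m"][i, j] = fit.m
        maps["r2"][i, j] = fit.r2
    return AmplitudeMaps(
        a_rex=maps["a_rex"],
        method="fit",
        a=maps["a"],
        b=maps["b"],
        phi0=maps["phi0"],
        m=maps["m"],
        r2=maps["r2"],
        failed=failed,
    )


def spatial_cv(map2d: np.ndarray, mask: np.ndarray) -> float:
    """Spatial coefficient of variation (std/mean) of a map inside a mask."""
    vals = map2d[mask]
    vals = vals[np.isfinite(vals)]
    return float(np.std(vals) / np.mean(vals))
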