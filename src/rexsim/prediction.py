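"""Empirical prediction of A_REX maxima positions, and peak extraction.

On resonance, the rotary-excitation amplitude oscillates with the total
spin-lock duration t_SL.  The maxima positions follow the empirical law

    t_SL(k) = eta / (2 * f_stim) * (k - kappa),   k = 1, 2, ...

with module constants eta = 1, 2, 2, 4 and kappa = 1/4, 1/2, 0, 0 for
S-SL, RE-SL, C-SL and B-SL respectively; the period of successive maxima is
eta / (2 * f_stim).  These constants are empirical signatures of the event
trains: the refocusing/phase-inversion pattern of each module fixes the
spacing and shift of the constructive-excitation condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ETA",
    "KAPPA",
    "PeakSet",
    "predict_tsl_max",
    "period_formula",
    "find_maxima",
    "prediction_deviations",
]

ETA = {"S-SL": 1.0, "RE-SL": 2.0, "C-SL": 2.0, "B-SL": 4.0}
KAPPA = {"S-SL": 0.25, "RE-SL": 0.5, "C-SL": 0.0, "B-SL": 0.0}


@dataclass(frozen=True)
class PeakSet:
    """Local maxima of an A_REX-vs-t_SL curve.

    ``positions`` (s) are parabolic-interpolated peak locations in
    increasing order; ``period_estimate`` (s) is the mean successive
    spacing, NaN (with ``period_defined=False``) when fewer than two peaks
    were found.
    """

    positions: np.ndarray  # s
    period_estimate: float  # s
    period_defined: bool


def predict_tsl_max(name: str, f_stim: float, k) -> float | np.ndarray:
    """Predicted t_SL (s) of the k-th A_REX maximum."""
    if name not in ETA:
        raise ValueError(f"unknown preparation module {name!r}")
    if f_stim <= 0.0:
        raise ValueError("f_stim must be positive")
    k = np.asarray(k)
    if np.any(k < 1) or not np.issubdtype(k.dtype, np.integer):
        raise ValueError("k must be a positive integer")
    out = ETA[name] / (2.0 * f_stim) * (k - KAPPA[name])
    return float(out) if out.ndim == 0 else out


def period_formula(name: str, f_stim: float) -> float:
    """Idealized spacing of successive A_REX maxima: eta / (2 * f_stim) s."""
    if name not in ETA:
        raise ValueError(f"unknown preparation module {name!r}")
    if f_stim <= 0.0:
        raise ValueError("f_stim must be positive")
    return ETA[name] / (2.0 * f_stim)


def find_maxima(t_grid, a_rex, min_rel_height: float = 0.1) -> PeakSet:
    """Extract local maxima of an amplitude curve.

    Peaks below ``min_rel_height`` times the global maximum are discarded
    (suppresses the shallow ripple of uncompensated modules).  Positions are
    refined by three-point parabolic interpolation on the local grid
    spacing.  The period estimate is the mean successive spacing.
    """
    t = np.asarray(t_grid, dtype=float)
    a = np.asarray(a_rex, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValueError("t_grid and a_rex must be 1-D of equal length")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("t_grid must be strictly increasing")
    if a.size < 3:
        return PeakSet(np.empty(0), math.nan, False)
    idx, _ = find_peaks(a, height=min_rel_height * float(a.max()))
    positions = []
    for i in idx:
        y0, y1, y2 = a[i - 1], a[i], a[i + 1]
        denom = y0 - 2.0 * y1 + y2
        offset = 0.5 * (y0 - y2) / denom if denom != 0.0 else 0.0
        step = 0.5 * (t[i + 1] - t[i - 1])
        positions.append(t[i] + offset * step)
    positions = np.asarray(positions)
    if positions.size >= 2:
        return PeakSet(positions, float(np.mean(np.diff(positions))), True)
    return PeakSet(positions, math.nan, False)


def prediction_deviations(name: str, f_stim: float, positions) -> np.ndarray:
    """Relative deviation of simulated maxima from the prediction law.

    Each peak position is matched to the nearest maximum index k and the
    signed relative deviation (t_sim - t_pred)/t_pred is returned per peak.
    """
    positions = np.asarray(positions, dtype=float)
    period = period_formula(name, f_stim)
    k = np.maximum(1, np.round(positions / period + KAPPA[name]).astype(int))
    pred = predict_tsl_max(name, f_stim, k)
    return (positions - pred) / pred
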