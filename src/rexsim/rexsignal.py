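"""REX signal model and amplitude estimators.

In the resonance condition the post-crusher longitudinal signal is a
sinusoidal function of the relative phase ``phi`` between the spin-lock
pulse and the stimulus,

    S_REX(phi) = a * sin(phi * m + phi0) * sqrt(2) + b,

with signed amplitude ``a``, offset ``b``, phase shift ``phi0`` and a
modulation factor ``m`` (unity exactly on resonance).  The detection metric
``A_REX`` is either the sample standard deviation of the signal over the
acquired phases (the sqrt(2) in the model makes the two agree for uniform
full-period sampling, up to the N-1 correction sqrt(N/(N-1))) or ``|a|``
from a nonlinear least-squares fit of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "RexSeries",
    "RexFitResult",
    "uniform_phases",
    "amplitude_std",
    "fit_rex",
    "amplitude_equivalence_check",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class RexSeries:
    """A phase series: signals S_REX(phi_n) with a reference level s0."""

    phases: np.ndarray  # rad
    signals: np.ndarray  # dimensionless
    s0: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.phases.shape != self.signals.shape:
            raise ValueError("phases and signals must have equal length")
        if self.s0 <= 0.0:
            raise ValueError("s0 must be positive")

    def __len__(self) -> int:
        return self.phases.size

    @property
    def normalized(self) -> np.ndarray:
        return self.signals / self.s0


@dataclass(frozen=True)
class RexFitResult:
    """Parameters of the sinusoidal model fit (normalized by s0)."""

    a: float  # signed amplitude
    b: float  # offset
    phi0: float  # rad
    m: float  # modulation factor
    r2: float  # coefficient of determination; -inf when not converged
    converged: bool = True

    @property
    def a_rex(self) -> float:
        """A_REX = |a| (the sign lives only in ``a``)."""
        return abs(self.a)


def uniform_phases(n: int) -> np.ndarray:
    """N phases uniformly spaced on [0, 2*pi)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * math.pi * np.arange(n) / n


def amplitude_std(series: RexSeries) -> float:
    """A_REX as the sample standard deviation (N-1 denominator) of the
    normalized signals over the acquired phases."""
    if len(series) < 2:
        raise ValueError("amplitude_std requires at least 2 phases")
    return float(np.std(series.normalized, ddof=1))


def _model(phases: np.ndarray, p: np.ndarray) -> np.ndarray:
    a, b, phi0, m = p
    return a * _SQRT2 * np.sin(phases * m + phi0) + b


def fit_rex(series: RexSeries) -> RexFitResult:
    """Nonlinear least-squares fit of the sinusoidal signal model.

    Initialization: ``b`` from the mean, ``a`` from the standard-deviation
    estimator, ``phi0`` from the first discrete Fourier harmonic, ``m = 1``;
    ``m`` is constrained to [0.5, 1.5].  A negative fitted ``a`` is folded
    into ``phi0`` post hoc so that ``a >= 0``.  On failure the result is
    flagged (``converged=False``, ``r2=-inf``) rather than silently wrong.
    """
    if len(series) < 5:
        raise ValueError("fit_rex requires at least 5 phases (4 free parameters)")
    ph = series.phases
    y = series.normalized
    b0 = float(np.mean(y))
    a0 = max(float(np.std(y, ddof=1)), 1e-12)
    # first harmonic: y - b ~ a*sqrt(2)*sin(phi + phi0) has
    # sum(y*exp(-i*phi))/N ~ (a/sqrt(2)) * exp(i*(phi0 - pi/2))
    c = np.mean((y - b0) * np.exp(-1j * ph))
    phi0_0 = float(np.angle(c) + math.pi / 2.0)
    p0 = np.array([a0, b0, phi0_0, 1.0])
    lo = np.array([-np.inf, -np.inf, -np.inf, 0.5])
    hi = np.array([np.inf, np.inf, np.inf, 1.5])
    try:
        sol = least_squares(lambda p: _model(ph, p) - y, p0, bounds=(lo, hi), method="trf")
    except Exception:
        return RexFitResult(np.nan, np.nan, np.nan, np.nan, -np.inf, converged=False)
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return RexFitResult(np.nan, np.nan, np.nan, np.nan, -np.inf, converged=False)
    a, b, phi0, m = sol.x
    if a < 0.0:
        a, phi0 = -a, phi0 + math.pi
    phi0 = math.remainder(phi0, 2.0 * math.pi)
    resid = _model(ph, np.array([a, b, phi0, m])) - y
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else (1.0 if ss_res == 0.0 else -np.inf)
    return RexFitResult(float(a), float(b), float(phi0), float(m), r2)


def amplitude_equivalence_check(series: RexSeries) -> float:
    """Relative difference |A_std - |a|| / |a| between the two estimators.

    For noiseless uniform sampling over an integer number of periods with
    m = 1 this equals sqrt(N/(N-1)) - 1 exactly.
    """
    a_std = amplitude_std(series)
    fit = fit_rex(series)
    return abs(a_std - fit.a_rex) / fit.a_rex
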