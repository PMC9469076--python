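# Methods

## Physical model

All dynamics are computed in the frame rotating at the RF carrier
frequency. The magnetization M = (mx, my, mz) is dimensionless, normalized
to M0 = 1, and evolves under

    dM/dt = M × ω_eff(t) − R(M),

with the effective field (rad/s)

    ω_eff(t) = ( 2π f_SL b1 cos φ_lock,
                 2π f_SL b1 sin φ_lock,
                 2π Δf0^static + γ ΔB0^stim sin(2π f_stim t + ϕ) ).

The transverse part is the spin-lock RF field (amplitude f_SL in Hz,
scaled by the B1+ factor b1); the longitudinal part combines a static
off-resonance Δf0^static (Hz) and the oscillating stimulus to be detected
(amplitude ΔB0^stim in Tesla, γ = 2.675221874×10⁸ rad s⁻¹ T⁻¹). Time is
absolute, referenced to the start of the first spin-lock segment, so the
stimulus phase evolves continuously across segments and instantaneous
pulses.

**Relaxation.** R decomposes M about the instantaneous effective-field
(lock) axis: the parallel component decays with T1ρ, the perpendicular
components with T2ρ. No recovery toward M0 is modeled — preparations last
≤ 250 ms, long T1 recovery is negligible on that scale and the output is
normalized. With the field identically zero there is no lock axis and the
decay falls back to the uniform T2ρ rate (a degenerate case no preparation
reaches). Defaults are T1ρ = 100 ms, T2ρ = 80 ms, chosen as
representative tissue/gel-scale rotating-frame constants; they are fully
configurable, and the tests show which conclusions are and are not
sensitive to them (see Limitations).

**Sign conventions.** dM/dt = M × ω with γ > 0; a constant field rotates
M by −|ω|t about the field direction. A_REX is invariant to the global
sign, the convention is fixed once for reproducibility. Rotations by hard
pulses are right-handed about the transverse axis
(cos φ_axis, sin φ_axis, 0).

**Hard pulses** (excitation and refocusing) are instantaneous and
relaxation-free, and do not advance the stimulus clock: a real refocusing
pulse lasts ~1 ms, far below one 20 ms stimulus period at 50 Hz.

**Adiabatic half passage.** The shaped excitation integrates a 3 ms
hyperbolic-secant RF amplitude along x′ with a tanh frequency sweep:
ω1(τ) = ω1max sech(βτ), Δω(τ) = −Δωmax tanh(βτ), τ = t/Tp − 1 ∈ [−1, 0],
with β = 6, ω1max = 2π·5 kHz and Δωmax = 2π·2 kHz. These values keep the
passage adiabatic at nominal B1 (final angle to x′ below 1°) and degrade
gracefully under B1 scaling (≈ 2° at b1 = 0.9, versus 9° for a scaled hard
pulse) — the property that motivates adiabatic excitation in the first
place. Relaxation is applied during the shaped pulse when enabled; the
ideal mode is an exact 90° rotation about y′.

## Preparation modules

All modules start with the excitation onto x′ (ideal by default) and end
with an ideal crusher that zeroes mx and my, so the preparation output is
mz alone. The final flip-back pulse of conventional T1ρ preparation is
omitted by design: the contrast of interest lives in the phase-dependent
longitudinal component. Total spin-lock time t_SL is split as:

| module | segments (fraction, lock phase)        | refocusing pulses |
|--------|----------------------------------------|-------------------|
| S-SL   | (1, +x′)                               | —                 |
| RE-SL  | (½, +x′)(½, −x′)                       | —                 |
| C-SL   | (½, +x′)(½, −x′)                       | 180° at t_SL/2    |
| B-SL   | (¼, +x′)(½, −x′)(¼, +x′)               | 180° at t_SL/4, 3t_SL/4 |

The refocusing pulses are applied about the initial lock axis +x′. This
choice was not assumed but *validated*: the period and shift of the
A_REX-vs-t_SL maxima (η = 1, 2, 2, 4 and κ ≈ ¼, ½, 0, 0) uniquely
fingerprint the event trains, and an enumeration of the candidate
axis/phase patterns shows that exactly one equivalence class reproduces
them — 180° about the lock axis with sign-alternating lock phases
(identically: 180° about y′ with constant lock phase). The orthogonal
variant refocuses the stimulus-driven excitation itself and collapses the
amplitude, which is how a wrong construction is caught immediately. The
1:2:1 B-SL split equals four equal quarters with phases (+,−,−,+).

## Estimators

A_REX is the sample standard deviation (N−1 denominator) of the N
phase-series signals normalized by the reference S0 (S0 = M0 = 1 in
simulation). Phases default to N = 10 points uniform on [0, 2π) for
sweeps and N = 20 for imaging stacks. The model fit uses trust-region
least squares with initialization b = mean, a = A_REX, φ0 from the first
discrete Fourier harmonic and m = 1, with m constrained to [0.5, 1.5]; a
negative amplitude is folded into φ0 post hoc so a ≥ 0. For a noiseless
series on a uniform full-period grid the two estimators differ exactly by
the finite-N factor √(N/(N−1)): noise inflates the standard deviation but
not the coherent fit amplitude, so their comparison doubles as a noise
diagnostic. Normalization by S0 precedes fitting.

## Numerical choices

* RK4 with fixed step dt = 20 µs: ≥ 1000 steps per stimulus period at
  50 Hz. The classical-order check (error ratio ≥ 8 on halving dt), norm
  conservation (<10⁻⁶ over 250 ms without relaxation) and an A_REX
  convergence gate (<0.1% change on halving dt, part of `rexsim selftest`)
  guard the step choice.
* Batched integration: sweeps advance thousands of (t_SL, phase, Δf0, …)
  combinations in lockstep through a vectorized RK4; grid points are
  chunked by duration so short preparations are not oversampled. Each spin
  is stepped with h = duration/⌈duration_max/dt⌉ ≤ dt. Results are
  bitwise reproducible for fixed grids.
* Peak extraction: `scipy.signal.find_peaks` with a relative height floor
  (default 0.1 of the global maximum, suppressing the shallow ripple of the
  uncompensated module) and three-point parabolic refinement; the period
  is the mean of successive spacings (≥ 2 peaks required, flagged
  otherwise).
* Half-amplitude offsets are referenced to the curve value at Δf0 = 0,
  located by linear interpolation between grid points and averaged over
  the positive and negative sides.
* Fit failures are flagged (r2 = −∞ / per-pixel failure mask), never
  silent.

## Synthetic imaging

`make_phantom` builds deterministic scenes: a circular mask with uniform,
linear-gradient (default 3.2 Hz/cm across a 15 cm field of view, i.e.
±24 Hz, with a mild radial B1+ droop) or hotspot (localized ≥ 50 Hz bump)
off-resonance profiles. The Bloch engine runs one preparation per distinct
(Δf0, B1+) pair, quantized to 0.5 Hz / 0.01 bins; the surrogate engine
fits the sinusoidal model on a coarse node grid of Bloch runs and
interpolates (a·e^{iφ0}, b, m) per pixel — on smooth scenes it tracks the
full engine to well under a percent at a fraction of the cost. Noise is
additive Gaussian on the magnitude images (seeded); no Rician floor, no
k-space encoding, no readout blurring, no motion. Passing tests therefore
validate the preparation physics and the estimators, not the imaging chain
of a real scanner.

## Problem sizes

The test and acceptance runs use the full published simulation grids where
the quantitative claims live — t_SL 0.5…250 ms in 0.5 ms steps, the
off-resonance range ±1 ppm (127.7 Hz/ppm at 3 T) in 0.004 ppm steps, and a
10-point stimulus-frequency grid (10…100 Hz) for the prediction-law
check — and reduced grids (coarser t_SL/f_SL, 16–32 px scenes) for unit
tests, a deliberate choice to keep the default suite desk-scale.

## Known limitations

* **Linear calibration range.** A_REX grows as sin of the accumulated
  nutation angle. At t_SL = 80 ms a 100 nT stimulus already drives ≈ 2.1
  rad, so the amplitude response saturates measurably at the top of the
  5…100 nT range: the linear-fit R² plateaus near 0.996 there regardless
  of relaxation, phase count or amplitude spacing, and exceeds 0.999 only
  for shorter spin-lock durations or smaller amplitude spans. Calibration
  protocols should either stay in the small-angle regime or fit the sine
  response directly.
* **Early maxima of RE-SL.** The first one or two maxima of the
  rotary-echo module are broad and skewed late relative to the
  η/(2 f_stim)·(k − ½) rule (the zeros at multiples of the full period are
  exact; the maxima between them are not symmetric while the excitation is
  still building up). The rule is asymptotically accurate for later
  maxima.
* **Relaxation shift of smooth maxima.** A decaying envelope moves a
  smooth maximum earlier by ≈ P²/(2π²T_eff) (P the curve period): ≈ 1 ms
  for B-SL at 50 Hz with the default constants, growing quadratically at
  lower stimulus frequencies. Cusp-like extrema (the compensated modules'
  zeros) do not shift. Rotating-frame relaxation constants of gels and
  tissue vary widely, so maxima positions quoted to sub-percent precision
  should be read with this in mind.
* Single-compartment Bloch only: no exchange, diffusion or
  Bloch–McConnell extensions, and no lab-frame simulation of the Larmor
  carrier.
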