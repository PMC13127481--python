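# Methods

This note documents the model, the algorithmic choices, the default
parameters and the known limitations of `puwave`.

## Signal model and conditioning

A recording is a uniformly sampled pair (P, U) — aortic pressure in
mmHg and flow velocity in m/s — typically at 500 Hz. Conditioning
follows the standard catheter-lab chain:

1. **Low-pass filtering.** 4th-order Butterworth at 62.5 Hz, applied
   forward-and-backward (`sosfiltfilt`) to both channels identically.
   Zero phase matters because every downstream marker is a timing or a
   slope; a causal filter would shift landmarks by several
   milliseconds. The cutoff leaves arterial waveform content
   (< ~30 Hz) untouched while removing electrical interference.
   Whether filtering precedes or follows ensemble averaging is
   configurable (`filter_before_ensemble`, default: before); for
   linear filters the two orders are equivalent up to boundary
   effects.
2. **Velocity-channel delay.** Velocimetric hardware lags the pressure
   channel; the calibrated delay (default 0, sanity-bounded below
   50 ms) is corrected by advancing U by the nearest whole sample; the
   sub-sample residual is recorded in the metadata rather than
   silently dropped.
3. **Beat detection.** Pressure-upstroke candidates are threshold
   crossings of dP/dt at 20 % of its global maximum. Each candidate is
   validated by requiring its local dP/dt peak to reach at least half
   the global peak — filtered noise occasionally grazes the threshold
   in diastole, and an unvalidated candidate can otherwise swallow a
   true upstroke through the refractory merge. Feet are refined by the
   intersecting-tangent method (tangent at peak dP/dt intersected with
   the preceding diastolic baseline) and deduplicated within a 250-ms
   refractory period. Beats whose cycle length deviates more than 15 %
   from the median are excluded with a reason code.
4. **Ensemble averaging.** The first five usable beats (configurable)
   are aligned at their feet and averaged sample-wise, truncated to
   the shortest cycle. Windows keep 100 ms of pre-foot baseline: the
   tangent foot can trail the true wave onset by up to a quarter of
   the upstroke duration on smooth waves, and point A must lie inside
   the window.
5. **Derivatives.** dP/dt and dU/dt are central differences over a
   2-ms step (`k = round(0.002·fs)` samples), one-sided at the ends,
   so derivative series have the length of the beat. mmHg↔Pa uses
   133.322; both it and the blood density ρ (default 1060 kg/m³, a
   standard whole-blood value) are configurable.

## Wave-intensity analysis

Net wave intensity is `(dP/dt)(dU/dt)` with dP/dt in Pa/s
(W·m⁻²·s⁻²). The linear separation at pulse wave speed c is

    Pf = (P + ρcU)/2      Pb = (P − ρcU)/2
    WIf = (dPf/dt)²/(ρc)  WIb = −(dPb/dt)²/(ρc)

Component derivatives are formed from the beat's dP/dt and dU/dt
directly, so `Pf+Pb = P`, `Uf+Ub = U` and `WIf+WIb = net-WI` hold to
machine precision for *any* c — these identities are property-tested
and are the package's most basic contract.

### Landmarks

* **A** — onset of the initial positive net-WI. The naive rule ("last
  non-positive sample before the peak") is exquisitely sensitive to
  zero-phase filter pre-ringing at the 10⁻⁶-of-peak level, so A is
  located by the same two-threshold template back-projection used for
  wave onsets (below).
* **B** — end of the initial positive net-WI: its first return to
  effectively zero (≤ 0.5 % of peak) after the peak, refined to the
  local velocity maximum within ±10 ms. This is deliberately *not*
  the global velocity maximum: a strong midsystolic forward wave can
  re-accelerate flow and produce a second velocity peak, and the
  acceleration time must end at the first one. A discrepancy larger
  than 10 ms between B and the global velocity maximum is logged as a
  data-quality warning.
* **C** — peak pressure after B. When pressure has no rise beyond B
  (reflection-free beats plateau), C falls back to its defining
  property, the onset of the second positive net-WI.
* **D** — first non-positive net-WI sample after the second positive
  net-WI peak.

Phases: 1 = [A,B), 2 = [B,C), 3 = [C,D). AcT = t(B) − t(A) using the
sub-sample A.

### Wave-onset estimation

Backward-wave onsets (and A) are found in two stages. *Detection*: the
first sample after A where the relevant intensity exceeds
θ = 0.5 % of peak WIf for 3 consecutive samples (`bcw_detect_frac`,
`bcw_min_samples`). *Refinement*: a raised-cosine-like wave rises as
`y = ymax·sin⁴(π(t−t0)/d)`, so t is linear in
`z = arcsin((y/ymax)^{1/4})` and the regression intercept of t on z is
the onset t0. The fit uses the samples between a noise-adaptive floor
(max of 5 % of θ and twice the pre-detection median — without the
adaptive part, separated-intensity noise drags the segment back to A)
and 80 % of the wave's amplitude. On noise-free single wavelets the
onset error is below one sample; a pure threshold crossing would be
~16 % of the wavelet duration late, enough to corrupt %Td outright.
The template assumption (smooth, compactly supported wavelet) is a
shape prior; composite reflections from several sites are slightly
mis-projected (a few ms early in our composite-reflection preset).

### Pulse wave speed and the S1 window

The water-hammer relation holds on the early upstroke until the first
backward wave — of either sign — arrives. Since that onset itself
requires a separation (which needs c), a fixed point is iterated:

1. a provisional slope over a greedy window grown from A while the
   P-U fit stays linear (R² ≥ 0.995, or residual RMS below 0.5 mmHg —
   about 3× the ensemble-averaged filtered noise at default noise
   levels, so shallow early windows are not rejected for noise);
2. separation at that c; 3. onset of the first backward wave;
4. refit over A → min(onset, B); repeat until c changes < 0.5 %
   (max 10 iterations). A pathological refit (onset collided with the
   foot under noise) falls back to the greedy window rather than
   failing.

Both PWS (from the iterated window) and S1 (the `fit_s1` slope over
A → min(first-backward-onset, B), |slope|/ρ) are reported; they
coincide on clean data. Using the *first backward wave* rather than
the BCW specifically keeps the window clean when an early backward
decompression wave precedes the reflection.

### Segmentation, quantification, timing

Waves are classified by phase window and derivative signs: initial FCW
(phase 1, dPf/dt > 0), BCW (backward compression run from the detected
onset while dPb/dt > 0), e-BDW (phase 1, dPb/dt < 0), m-FCW / m-FDW
(phase 2, dPf/dt > / < 0), l-FDW (phase 3, dPf/dt < 0). Absent waves
are reported with zero magnitude, never omitted. Cumulative intensity
is the trapezoidal time integral over the wave's run; every wave's
relative magnitude divides its |cumulative| by the cumulative initial
positive net-WI (the positive part of net-WI over [A,B)). Summary
scalings: peaks in 10⁴ W·m⁻²·s⁻², cumulative in 10² W·m⁻²·s⁻¹.
%Td = Td/AcT with Td from A (sub-sample) to the BCW onset
(sub-sample); no supra-threshold BCW → flagged absent, not an error.
Phase deltas (ΔPb, ΔPf over phases 1 and 2) are endpoint differences
of the component pressures and are offset-invariant, so the absolute
baseline convention of the separation cannot affect them.

### PU-loop markers

S2 is the least-squares slope of P (Pa) on U over [B, C], |slope|/ρ
(a two-point secant is available via `s2_two_point` for sensitivity
analysis); U normally falls while P rises there, so the raw slope is
negative and markers are reported as absolute values, with composites
S1+S2 and S2:S1. A–B bending is judged against the extrapolated
water-hammer line (slope ρ·PWS — stable, unlike a short-window refit
whose noise tilt eats the margin), anchored on the clean initial
window; the classifier takes the mean signed pressure residual over
the half of the post-window limb adjacent to B, where the deviation
actually lives (a whole-limb mean dilutes even an unmistakable bend),
against a ±1 mmHg tolerance.

## The simulator

Each forward or backward wavelet contributes a raised-cosine-squared
lobe to dPf/dt or dPb/dt (lobe integral = its pressure increment, in
mmHg); the reflection returns the initial forward wavelet scaled by
R ∈ [0,1) and delayed by τ; components integrate in closed form; and
U = (Pf−Pb)/(ρc). Cycles close with a linear end-diastolic relaxation
of both components and a 20-ms quiet gap before the next upstroke so a
true net-WI zero precedes A. Gaussian noise and the velocity-channel
delay are applied last; every draw is governed by the scenario seed.
Ground truth carries the exact component pressures, the analytic
cumulative intensity of each wavelet (1.5·Δp²/(d·ρc)), the expected
AcT (first velocity peak), %Td (= τ/AcT) and the reflection's R²
energy ratio.

Defaults: ρ 1060 kg/m³, diastolic pressure 67 mmHg, 75 bpm, 500 Hz,
8 beats, 0.3 s lead-in, noise 0.5 mmHg / 0.005 m/s (catheter-lab
scale).

**Presets.** `non_cad`: c = 6 m/s, 55-mmHg initial compression,
R = 0.25 arriving at ~90 % of AcT, a −6-mmHg midsystolic forward
decompression wave, a nominal −1-mmHg early backward decompression
wave. `cad_ht`: c = 9.5 m/s, 45-mmHg initial compression, R = 0.3 at
~70 % of AcT, an 8-mmHg midsystolic forward compression wave sized so
its relative magnitude is ≈ 0.07, and a small sharp proximal
reflection (3 mmHg over 60 ms) so the backward pressure has risen
~2 mmHg by peak velocity — the stiff-aorta feature that bends the A-B
limb upward. The occlusion pair switches one base scenario between a
late/small and an early/large reflection. Amplitudes were chosen so
the phase-wise component-pressure changes fall in the reported
physiological ranges; the closing late decompression wave is sized
automatically so velocity returns to zero at end-systole.

**Cohorts** draw per-subject parameters log-normally
(median-preserving) around the presets with coefficients of variation
0.2 (speed, amplitudes, reflection), 0.1 (delay), 0.08 (heart rate).
Midsystolic *compression* waves scale with both the amplitude and the
reflection factor: the m-FCW is a compensatory response to backward
load, and uncoupled draws would let it re-accelerate flow past the
early-systolic velocity peak, which real recordings do not show.

## What the simulator does and does not emulate

It reproduces the wave-superposition skeleton of a central-aortic
recording: timing, amplitude and energy relations between forward and
backward waves, water-hammer-consistent velocity, sensor noise and
channel delay, beat-to-beat replication. It does **not** model
nonlinear convective effects, pressure-dependent wave speed,
multi-site distributed reflection (a single discrete site plus one
optional proximal wavelet), respiratory or autonomic beat-to-beat
variability, catheter artifacts (whip, damping), or ectopy. Passing
parameter-recovery tests therefore demonstrates the *analysis* is
correct under the linear model, not that every clinical waveform will
be segmented as cleanly; %Td in particular inherits a few-ms onset
bias when reflections are composite.

## Statistics

Nonparametric throughout, matching small-cohort practice: quantiles by
linear interpolation; Mann-Whitney p exact (full enumeration) for
tie-free n₁+n₂ ≤ 12 else normal approximation with continuity and tie
correction, with effect size r = |Z|/√N from the tie-corrected Z
without continuity correction; Fisher two-sided by probability
ordering; Spearman with average ranks and t-approximation p; empirical
ROC over midpoint thresholds, trapezoidal AUC (equal to U/(n₁n₂)),
Youden cutoff with ties broken toward specificity. The marker panel
reports markers that are *lower* in cases with a flipped decision rule
(direction "<=") so AUCs read as discriminative ability. No
multiple-testing correction is applied anywhere. Printed p-values
floor at "<0.001" and cap at "0.999"; full-precision values are always
retained.

## Numerical edge cases

Non-uniform time grids are rejected at read time; constant-velocity
loops are flagged degenerate; B = C makes S2 undefined (flagged, not
an error); a missing BCW yields an absent %Td; all-zero velocity or a
negative initial slope raise estimation errors; landmark ordering
violations raise with diagnostics. Sub-threshold waves quantify to
zero. S2:S1's monotone response to the midsystolic wave holds in the
regime where midsystolic flow still decelerates monotonically; beyond
it the B→C limb hooks and a least-squares slope is no longer a
monotone functional (documented, and the graded-series analyses stay
inside the regime).

## Problem sizes

Validation uses 8-beat recordings at 500 Hz (~7 s), a 4×3×2 recovery
grid, and twenty 31-subject cohorts; the full suite and the acceptance
script each run in well under a minute on one core.
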