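# Methods

This note documents the models, estimators, numerical choices and
limitations of `fwavetilt`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal model

The atrial component of the ECG during AF is modelled, on short windows, as
a fundamental plus second harmonic with common instantaneous frequency:

    s(n; θ) = Σ_{p=1,2} A_p exp(j(2π p f n / fs + φ_p)),    θ = [f A1 A2 φ1 φ2]ᵀ.

The fundamental *f* varies slowly in time; its respiration-linked component
is the quantity of interest.  The synthetic generator realizes exactly this
structure: the true frequency is

    f_true(t) = Ff_mean + mod_amplitude · sin(2π FRR t) + drift(t),

with an Ornstein–Uhlenbeck drift (time constant 30 s), and the rendered
real signal is `A1 cos(ϕ) + A2 cos(2ϕ + φ)` with ϕ the integral of f_true.
Fitting the complex model to the discrete-Hilbert analytic signal of the
50 Hz f-wave signal is therefore consistent by construction.

## Frequency-trend estimation

For a candidate *f* the amplitudes/phases are linear (complex least
squares on the two-column basis), so the ML fit reduces to a 1-D search:
a 0.01 Hz grid over [f₀ − 1.5, f₀ + 1.5] followed by golden-section
refinement to 10⁻⁴ Hz (ties broken toward lower f; the per-window search is
vectorized across all windows, sharing the grid basis).  f₀ is the largest
Welch peak in 4–12 Hz (10-s Hamming segments, 50 % overlap → 0.1 Hz
resolution on 2-min phases), computed once per recording.  Windows are
0.5 s (25 samples) hopped one sample (20 ms), which is what makes the trend
a 50 Hz series; the first/last 0.25 s have no centred window and are
invalid.

**Quality index.**  Each trend sample's model value at its window centre
forms a reconstruction series; per non-overlapping 5-s block,
S = 1 − σ_ê/σ_xa with complex standard deviations.  Blocks with S ≤ 0.3
are invalidated; a recording with > 10 % bad blocks is excluded.  The
complex (not real-part) residual is used; a trailing partial block inherits
the validity of the last full block.  Per-phase Ff is the median over valid
samples, requiring ≥ 50 % valid coverage (configurable).

## Preprocessing

* **Beat detection**: 5–30 Hz zero-phase band-pass, squared, 120-ms
  moving-average envelope, peak picking at 10 % of the envelope's 99th
  percentile with a 200 ms refractory period, refined to the local
  filtered-signal extremum.  The band reaches down to 5 Hz so wide
  (ventricular-origin) ectopic complexes keep detectable energy.
* **Ectopic classification**: two-pass median-beat template; a beat is
  ectopic when its correlation with the template over the QRS sub-window
  (R ± 100 ms) falls below 0.9, or its RR interval deviates > 50 % from the
  local (11-interval) median RR.  The correlation is evaluated on the QRS
  sub-window because f-waves and noise in the full QRST window put a floor
  under attainable correlations that would dominate the decision; the RR
  rule skips intervals touching a morphology-flagged beat so a mislocated
  ectopic R peak cannot flag its normal neighbours.  At AF-like RR
  irregularity (CV 0.15) the 50 % threshold keeps the false-flag rate of
  normal beats below ~1 %.
* **QRST cancellation**: average-beat subtraction.  The template window is
  −100…+430 ms around R — in AF there is no P wave before the QRS, and a
  window contained in one RR interval at fibrillatory rates avoids template
  overlap between adjacent beats (a wider window smears the neighbouring
  T wave into the template's edges and doubles-subtracts it).  Each beat is
  aligned to the template (integer search ± 10 ms plus parabolic sub-sample
  refinement, template shifted by fractional-delay interpolation) and
  fitted with three least-squares regressors: QRS gain (|t| ≤ 120 ms),
  T-wave gain, and a constant that absorbs local baseline but is **not**
  subtracted (subtracting it would remove the local f-wave mean and leave
  per-window steps).  Ectopic-beat windows are replaced by linear
  interpolation; the replaced-sample mask is propagated so that trend
  samples whose fitting window touches them are marked invalid — those
  stretches carry no atrial signal, and scoring them as data was the single
  largest noise source in early versions (fits there are unconstrained and
  can land anywhere in the ±1.5 Hz interval).
* **Resampling**: zero-phase 10th-order Butterworth low-pass at 23 Hz, then
  polyphase rational resampling to exactly 50 Hz; output length is
  ⌊duration·50⌋.  A 30 Hz tone is attenuated by far more than 40 dB;
  in-band (4–12 Hz) energy is preserved within 2 %.
* **Heart rate**: FHR = 60 / mean(RR) over intervals between consecutive
  non-ectopic beats fully inside the phase, dropping intervals adjacent to
  an ectopic beat.

## ECG-derived respiration

Respiration modulates QRS morphology.  Per lead and non-ectopic beat the
slope range (max − min of the first-difference derivative over R ± 50 ms)
is computed after a 35 Hz zero-phase low-pass — differencing amplifies
broadband noise quadratically with frequency, and without the pre-filter
the derivative extremes are noise, not QRS slopes.  Beat series are
cubic-spline interpolated to 50 Hz, linearly detrended and band-passed to
0.08–0.5 Hz.

πCA then finds the lead combination w minimizing
ε(τ) = wᵀA_τw / wᵀCw (A_τ: covariance of the τ-lagged difference; C: lead
covariance) over integer lags corresponding to a 0.01 Hz frequency grid in
the scan band.  Numerically this is solved by whitening against the
principal subspace of C (eigendirections below 10⁻¹⁰ of the largest are
excluded) rather than ridge regularization: with duplicated or collinear
leads a ridge turns the zero-energy difference direction into the
minimizer and returns a null signal, whereas subspace whitening stays well
posed.  A signal periodic at lag τ is also periodic at its multiples, so
among essentially tied minima (within 5 %) the smallest lag wins —
otherwise a subharmonic can capture FRR/2.  FRR = fs/τ*; r(m) is
unit-variance with the dominant weight made positive.  πCA runs per phase
segment, matching per-phase FRR reporting.

## Orthogonal subspace projection

V has q+1 columns, each a one-sample-delayed copy of r(m) (column d holds
r(1+d)…r(M−q+d)); f̃ is the mean-subtracted trend truncated to M−q.  The
projection f_r = V(VᵀV)⁻¹Vᵀf̃ is computed by SVD least squares with a
**relative singular-value cutoff of 0.05**: the delay matrix of a
narrowband respiration signal is numerically full rank only through its
noise, and projecting at machine-precision rank hands (q+1)/(M−q) of the
broadband trend-noise energy to f_r — with q ≈ 90 that is a ΔFf noise
floor of ~0.025 Hz, comparable to the physiological effect.  The cutoff
keeps the dominant (quadrature-pair) directions and discards noise
directions; well-conditioned delay matrices (e.g. white-noise r, where the
smallest singular value is ~half the largest) are untouched, so the
projection coincides with the plain pseudo-inverse there.

Defaults: q = round(fs/(4·FRR)) — a quarter respiratory period, spanning a
90° phase shift of the narrowband respiratory component; invalid-trend gaps
≤ 5 s are bridged by linear interpolation (the delay matrix needs uniform
sampling), longer gaps truncate to the longest contiguous usable run, and
runs < 60 s yield a missing value.  ΔFf = √(2‖f_r‖²/(M−q)) equals the
amplitude of an equal-power sinusoid; Pr = 100‖f_r‖²/‖f̃‖².

Sensitivity to q (not assumed, measured in the monotonicity tests): ΔFf is
stable for q between an eighth and a half respiratory period; the noise
floor grows with the retained subspace dimension, which the singular-value
cutoff, not q itself, controls.

## Activation-time analysis

Per point, instantaneous frequency is the reciprocal cycle length
attributed to the interval midpoint, linearly interpolated onto a uniform
10 Hz grid over the point's activation span (points with < 3 activations
are dropped; inter-activation intervals ≤ 30 ms indicate corrupt input and
are rejected).  Peak-conditioned selection retains a point when ≥ 25 % of
its linearly detrended Welch-spectrum power (bins ≥ 0.05 Hz) lies within
± 0.05 Hz of the spectral peak; the averaged trend uses retained points
only, each contributing where its span covers the grid.  Ffs is the time
median of the average; ΔFfs applies the OSP machinery with
r(m) = sin(2π·0.14·t) as the reference — the simulation side has no
measured respiration, the modulation frequency is known.  The analysis
window defaults to the full series; a final-window restriction is
available in the configuration but is subject to the same ≥ 60 s minimum
the OSP estimate needs (about eight respiratory cycles at 0.14 Hz).

## Statistics

* **Wilcoxon signed-rank** (two-sided): zeros dropped, midranks for tied
  magnitudes; exact null enumerated over all 2ⁿ sign patterns for n ≤ 15
  (p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1); normal approximation with
  continuity and tie corrections for larger n.
* **Lilliefors**: KS statistic against a normal with sample-estimated
  moments; p-value from a cached Monte-Carlo null (10,000 standard-normal
  samples per sample size, internally seeded) — its measured type-I error
  at α = 0.05, n = 24 is within [0.03, 0.07].  Against an exponential
  alternative at n = 24 the power is ≈ 0.66 (the statsmodels reference
  implementation agrees), i.e. moderate, not high.
* **Comparisons**: nine default pairs (five consecutive sub-phase steps,
  two transient-to-transient, two steady-to-steady); per metric and pair a
  paired Wilcoxon on patients with both phases present; significance at
  α/9.  Response classification per patient: minimal if the relative change
  is < 1 % (absolute change against 1 % of the cohort median when the
  previous value is zero).
* **Summaries**: mean ± SD when Lilliefors is compatible with normality
  (p ≥ 0.05), else median (Q1–Q3) with linear-interpolation quartiles.

## Synthetic study conditions

Defaults are calibrated to the six-phase clinical medians: per phase,
Ff_mean = 6.74/6.69/6.49/6.55/6.77/6.72 Hz, respiratory modulation
amplitude 0.077/0.070/0.090/0.063/0.081/0.079 Hz, respiration rate
0.13/0.13/0.15/0.16/0.12/0.15 Hz, mean heart rate
93.5/89.75/90.25/93.5/98.5/96 bpm; phase durations 120/180 s ×3; ectopic
rate 1.07 % of beats.  Choices the data do not pin down, made once:

* Records are generated at 500 Hz (analyses accept any rate ≥ 250 Hz; the
  resampling and trend contracts are tested at 1 kHz as well).
* RR intervals are i.i.d. log-normal with CV 0.15 — AF has weak serial RR
  correlation, and such cohorts are predominantly rate-controlled under
  beta-blockade, hence moderate rather than extreme irregularity.
* f-wave amplitudes A1 = 0.10 mV, A2 = 0.035 mV on V1, with a 3× smaller
  projection on other leads (V1 is the atrial analysis lead); QRS 1 mV,
  T wave 0.3 mV, sum-of-Gaussians templates; ectopics are widened (×1.9)
  and polarity-inverted.
* White noise of 0.08 mV at the record rate puts the 5-s quality index S
  around 0.5–0.6, so the S > 0.3 gate is exercised but rarely triggered on
  clean records; noise bursts are injected explicitly in the gate tests.
* OU drift SD 0.02 Hz, clipped so f_true stays inside the constrained
  search interval.
* The f-wave and respiratory phases are integrated continuously across
  phase boundaries, so a six-phase record behaves like one recording whose
  parameters step at the tilt transitions.

What the generator does **not** emulate: baseline wander and electrode
artefacts, multi-lead f-wave morphology differences beyond a gain,
inter-patient template variability, RR–f-wave interaction, and any
mechano-electrical feedback.  Passing the recovery tests therefore shows
the chain is correct and well-calibrated under its own model class, not
that clinical effect sizes would be recovered at clinical noise levels —
in particular Pr here (10–20 %) is far above clinically reported values
(2–3 %) because the synthetic trend is much cleaner than a clinical one.

## Problem sizes used in validation

The end-to-end recovery and direction studies use 20 independent 15-minute
recordings; the modulation sweep uses 20 three-minute single-phase
recordings per amplitude level {0, 0.025, 0.05, 0.08, 0.1} Hz; activation
recovery uses 223-point, 120-s sets with 30 % broadband points; the
Lilliefors calibration uses 1000 samples of n = 24.  The reproduction
script defaults to 10 recordings per study (about one minute of runtime)
with the same conditions.

## Known limitations

* The QRST cancellation is single-lead average-beat subtraction; coupled
  multi-lead or PCA-based cancellation is out of scope.
* Equivalence with the proprietary preprocessing used on the original
  clinical data cannot be tested; the ectopic rule and cancellation are
  openly specified stand-ins with thresholds in the configuration.
* The exact peak-conditioned selection rule of the cited activation-series
  literature is not public; the spectral-concentration criterion here is an
  openly specified replacement (threshold configurable).
* ΔFf from Eq.-type average-peak-amplitude estimators carries a positive
  noise floor; the singular-value cutoff controls but does not remove it.
  Null-modulation data yield ΔFf ≈ 0.004 Hz under the default conditions
  (measured, not derived).
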