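# Methods

This note documents the models, estimators and numerical choices behind
`mfr`, in the order the pipeline uses them.

## Stimuli and the 2σ = 1 convention

All Gaussian inputs (band-limited stimulus, OU noise) are rescaled after
generation so their sample standard deviation is exactly 0.5.  An amplitude
`A` multiplying such a signal then spans ±A around the mean about 95 % of
the time, which makes "relative modulation amplitude" statements exact per
realization rather than in expectation.

**Band-limited Gaussian noise** is constructed in the frequency domain:
independent complex-Gaussian Fourier coefficients on 0 < f ≤ cutoff, zero
elsewhere, inverse transform.  This gives a genuinely flat spectrum with a
brick-wall edge; a time-domain filter would leave roll-off and stop-band
leakage, which matters because several analyses hinge on the input having
*no* power above the cutoff.  Generation is rejected when the run is
shorter than two periods of the lowest resolvable frequency.

**Ornstein–Uhlenbeck noise** uses the exact discretization
x[k+1] = e^(−dt/τ)·x[k] + √(1−e^(−2dt/τ))·ξ[k] (run through
`scipy.signal.lfilter`), so its statistics are independent of the step
size.  Two canonical correlation times are used: τ_n = 1 ms ("fast") and
τ_n = 100 ms ("slow").  The closed-form lag-τ autocorrelation e⁻¹ is a
test oracle.

## Neuron models

The membrane equation is C·dV/dt = −(V−E_R)/R − I_B + I_E with spike and
reset to E_R at V ≥ V_th.  Defaults are the granule-cell-fitted constants
C = 3 pF, R = 5227 MΩ (τ = 15.7 ms), E_R = −71.5 mV, V_th = −41.8 mV;
rheobase (V_th−E_R)/R = 5.68 pA.  The resonant variant adds
I_B = g_b·b·(V−E_R), where the dimensionless resonant state b jumps by 1
at each spike and decays with τ_b = 19.6 ms, plus a spike output delay
Δ_s = 4.85 ms applied to recorded spike times only (a pure phase delay
with no effect on the dynamics).  The state increment is b → b+1 per spike
(so the active conductance is g_b·b, in pS); the alternative reading of
the resonance equation as a jump of 1/τ_b gives currents three orders of
magnitude too small to matter and inconsistent units, and is rejected.
No refractory period is modelled.

**Integration** is exponential Euler at dt = 0.025 ms: within each step
the drive and conductance state are frozen and the linear membrane ODE is
advanced exactly.  For the passive cell (and the resonant cell with
g_b = 0) this reduces to a single precomputed decay factor, and the two
code paths are literally the same kernel, which is why the resonant model
with g_b = 0, Δ_s = 0 reproduces the passive model bit-for-bit.  Threshold
crossings are detected at the end of a step and the reset applied
immediately.  This quantizes each crossing to the grid: individual ISIs at
constant drive are accurate to one dt, but absolute spike times in long
modulated runs accumulate a sub-millisecond quantization walk (~1 ms over
5 s), which is inherent to end-of-step detection, not an integrator error.
The time-stepping loops are numba-compiled; a pure-Python loop would be
~100× slower and make the 120-s population runs impractical.

The **ideal encoder** integrates the rectified rate signal
(max(R, 0)·dt, in spikes) and emits a spike each time the accumulator
crosses 1.  Clipping negative instantaneous rates to zero at this point is
deliberate: it *is* the rectification phenomenon that push-pull coding is
designed to counter, so it must not be hidden upstream in the rate-signal
construction.

## Calibration

Tonic currents are found by bisection on simulated steady rates (10-s
runs, 1-s warm-up, rate read from inter-spike intervals, tolerance 0.5 %).
The modulation amplitude for relative amplitude a is defined as
A_I = I((1+a)·F₀) − I(F₀) through the same calibration.  Noise amplitudes
can be specified either through the analogous rate-calibrated convention
(A_IN = I((1+a_n)F₀) − I₀) or as an absolute current in pA; the
interpretation is a config option because the two conventions diverge for
subthreshold operating points.

**Low-rate populations**: each cell draws a target effective rate from a
truncated-at-zero Normal(4, 2) spikes/s; the modulation amplitude is fixed
at A_I = 2 pA and the per-cell tonic current is bisected *with modulation
and noise active* (30-s calibration window, 1-s warm-up) until the
measured F_eff is within 10 % of target (absolute floor 0.1 spikes/s,
since spike counts at ~0.1 spikes/s quantize coarsely).  For the
slow-noise condition the per-cell OU amplitude defaults to 2 pA — the same
scale as the fixed modulation; the reference description states only that
the noise amplitude was adjusted together with the tonic currents, so this
value is a package choice, made once and recorded here.

## Population output and the analysis grid

The decoded population signal is the sum of sampling-rate-filtered trains
(binary per cell on the 0.025-ms grid); under push-pull coding it is the
difference of the two sub-population sums.  After discarding a 1-s
warm-up, both x and y are moved to a 1-ms analysis grid.  The spike output
goes through zero-phase FIR anti-aliased decimation
(`scipy.signal.decimate`): a spike train carries broadband shot power far
above the analysis band, and plain per-bin counting folds that power into
0–500 Hz, inflating the incoherent floor — on the single-cell baseline it
biases mean VAF down by ~12 percentage points, while anti-aliased
decimation agrees with full-rate analysis to ~0.2 points.  The
band-limited input is subsampled directly (it has no power anywhere near
the new Nyquist rate).

## Spectral estimation

Welch's method with 2-s Hann segments, 50 % overlap and per-segment mean
removal (so the carrier offset cannot leak into the lowest bins), giving
0.5-Hz resolution — the lowest evaluated frequency.  Transfer functions
are T = P_xy/P_xx with gain normalized to unity at the lowest analysis
frequency and unwrapped phase in degrees, lags negative.  The Wiener
filter K = P_yx/P_yy is zeroed where the input power falls below 10⁻¹² of
its peak (those bins carry no stimulus and are unreconstructable);
reconstruction applies K in the frequency domain, non-causally.  VAF is
computed directly from the cross-spectra (magnitude-squared coherence, in
percent); its identity with the realized reconstruction-error variance is
a test, not the definition.  The mean VAF over the band from 0.5 Hz to the
input cutoff weights bins uniformly; that choice (rather than
power-weighting) is recorded in result metadata.

Two estimator artifacts are worth knowing about.  (1) Per-bin coherence
estimates with ~120 averaged segments still show isolated outliers
(e.g. 12 % in a band whose true level is ~2 %), so claims about VAF
*levels* are asserted on 2-Hz block averages.  (2) Coherence is invariant
under linear filtering of the output only when the Welch segment is long
relative to the filter's memory; for the τ_α = 100 ms alpha filter the
default 2-s segments leave up to ~10-point deviations in the lowest bins,
while 8-s segments bring the maximum deviation below one point.

## Analytic transfer function of the noise-free leaky IF

Linearizing the threshold-crossing condition of a periodically firing
leaky IF (steady ISI T, membrane time constant τ) for a small multiplicative
current modulation at angular frequency w gives two closed forms used as
oracles:

- instantaneous-rate readout (the sinusoid-fit regime):
  H_rate(w) = (e^(T/τ) − e^(−iwT)) / (T·(1/τ + iw));
- delta-train readout (the direct/sampling-rate regime):
  H_train(w) = iw·(e^(T/τ) − e^(−iwT)) / ((1/τ + iw)·(1 − e^(−iwT))),

the latter with poles at multiples of the firing rate — the spike-locking
resonance peaks seen in white-noise transfer estimates.  Both reduce to
the same quasi-static limit, which equals the slope of the f-I curve.  The
measured sinusoid fit agrees with H_rate to better than 1 % in gain ratio
and ~0.1° in phase at 5 Hz; the direct estimate follows H_train within
1 dB below the Nyquist rate.

## The sinusoid-fit method and why it is kept

`sinusoid_fit_transfer` implements the classical Bode-plot procedure: a
linear least-squares fit of c + A·sin(2πft+φ) to the instantaneous firing
rate at the *known* stimulus frequency.  It is retained deliberately as a
foil: above half the carrier rate it keeps returning finite gain (the fit
is told the answer's frequency) while the coherence-based VAF in the same
band is near zero — prior knowledge no downstream decoder could have.

## Experiment conditions and problem sizes

A config plus seed list determines a run exactly; per-cell random streams
are derived as SeedSequence(seed, spawn_key=(stream, cell)).  Runs use
120 s per seed and three seeds per condition, with 1 s warm-up discarded —
long enough that ~120 Welch segments keep the coherence bias (≈1/K) below
one percentage point, and the per-seed spread of mean VAF is ~1–3 points
in the least favourable (low-rate) conditions.  The cutoff-vs-rate
frontier sweep bisects the stimulus cutoff to 1 Hz per target rate using
60-s single-seed evaluations of N = 100 encoder populations; points where
even the lowest cutoff fails the 90 % VAF threshold are reported censored.
The low-rate reference condition does not restate its stimulus cutoff;
20 Hz (the baseline of the preceding conditions) is used and recorded in
the config.

## What the synthetic conditions do and do not show

The generators emulate the study's idealized inputs: stationary Gaussian
band-limited stimuli, OU noise currents, deterministic or Poisson rate
encoders with heterogeneous carriers.  Real mossy-fiber input differs in
ways these tests cannot speak to — non-stationary statistics, synaptic
short-term dynamics (facilitation/depression), conductance rather than
current drive, and correlated inhibitory feedback.  Passing results show
that the *estimation machinery* is unbiased and that the simplified cells
transmit as claimed under the stated input statistics; they do not certify
the detailed biophysics.  A detailed conductance-based neuron can be
plugged in through the same `simulate()` contract (drive in, spike times
out) to close part of that gap.

## Known limitations

- Spectral estimation is Welch-only (no multitaper or parametric option).
- The resonant model's threshold is taken equal to the passive model's
  (−41.8 mV); the reference description does not restate it.
- The sinusoid-fit error surface is quadratic and solved in one linear
  least-squares step; no iterative refinement of frequency (by design —
  the frequency is an input).
- Very low target rates (< ~0.5 spikes/s) calibrate coarsely: a 30-s
  window contains too few spikes for a 10 % tolerance, and the absolute
  floor of 0.1 spikes/s takes over.
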