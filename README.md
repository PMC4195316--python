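# mfr — modulated firing-rate coding: simulation and ideal-observer analysis

`mfr` asks a concrete question from cerebellar physiology: can a spiking
neuron that encodes a continuous sensory signal as *modulation of a tonic
firing rate* transmit that signal faithfully and linearly?  The package is
aimed at computational neuroscientists who want to quantify rate-coding
fidelity for integrate-and-fire-class models — single cells and populations,
with additive noise and push-pull coding — without committing to a detailed
conductance-based model.

## The method

A band-limited Gaussian stimulus x(t) (flat spectrum up to a cutoff,
normalized so 2σ = 1) drives a model cell as a current
I(t) = I₀ + A_I·x(t), where I₀ is calibrated to produce a carrier rate F₀
and A_I is the current that would raise the tonic rate to (1+a)·F₀ — the
relative modulation amplitude *a*.  The spiking output y(t) is read through
a *sampling-rate filter* (a binary train on the simulation grid) and the
transmission is quantified by two spectral statistics computed with Welch's
averaged periodogram:

- the **direct transfer-function estimate** T(f) = P_xy(f) / P_xx(f),
  reported as normalized gain (dB) and phase (degrees);
- the **ideal-observer reconstruction**: the non-causal Wiener filter
  K(f) = P_yx(f) / P_yy(f) and its fidelity, the variance-accounted-for

      VAF(f) = |P_xy(f)|² / (P_xx(f)·P_yy(f))   (in %),

  i.e. the magnitude-squared coherence.  The headline statistic of every
  experiment is the mean VAF over the stimulus band.

Three neuron models are built in: a passive leaky integrate-and-fire cell
(C = 3 pF, R = 5227 MΩ, τ = 15.7 ms, reset/rest −71.5 mV, threshold
−41.8 mV, rheobase 5.68 pA — constants fitted to a cerebellar granule
cell), a resonant variant with a spike-triggered decaying conductance
(g_b = 55.6 pS, τ_b = 19.6 ms) plus a 4.85-ms spike output delay, and the
ideal (leak-free, unit-threshold) integrator used as a rate-to-spike-train
encoder.  Populations support heterogeneous carrier rates, per-cell
Ornstein–Uhlenbeck noise currents, and push-pull coding (half the cells
receive −x(t); the decoded output is the difference of the sub-population
sums).

## Worked example

```python
from mfr import ExperimentConfig, run_current_experiment

config = ExperimentConfig(model="lif", n=1, f0=40.0, a=0.1,
                          cutoff_hz=20.0, duration_s=120.0, seeds=(1, 2, 3))
result = run_current_experiment(config)
print(f"mean VAF  = {result.mean_vaf:.1f} +- {result.sem_vaf:.1f} %")
print(f"F_eff     = {result.f_eff_mean:.1f} spikes/s")
print(f"I0 = {result.calibration['i0_pa']:.2f} pA, "
      f"A_I = {result.calibration['a_i_pa']:.2f} pA")
```

prints

```
mean VAF  = 96.8 +- 0.1 %
F_eff     = 40.0 spikes/s
I0 = 7.14 pA, A_I = 0.28 pA
```

A single 40 spikes/s cell reconstructs a 20-Hz band-limited signal almost
perfectly (the carrier is exactly twice the highest stimulus frequency, so
the spike code samples at its Nyquist rate); the calibrated tonic current
sits ~1.5 pA above rheobase and a 10 % modulation needs only ~0.3 pA.
Dropping the carrier to 20 spikes/s halves the usable band and the mean
VAF falls to ~48 %; populations of low-rate cells recover fidelity through
heterogeneity, noise and push-pull coding (see `mfr.experiments.CONDITIONS`
for the named reference conditions).

The same pipeline is scriptable from the shell:

```sh
mfr reproduce if_baseline --seed 1 --n-seeds 3 --plot
mfr sweep --model ideal -a 1 --rates 10,20,40
```

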