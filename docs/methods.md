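# Methods notes

This note documents the models, parameter choices, numerical conventions and
known limitations of the package, in the spirit of the model documentation
shipped with simulation and statistics libraries.

## Units and sign conventions

Voltages are mV (current clamp), currents pA (voltage clamp), distances µm,
rates Hz. Time is stored in seconds and reported in ms. Raw voltage-clamp
traces keep the physiological sign — inward synaptic currents are negative at
a −60 mV holding potential — while every reported "amplitude" is a magnitude
in pA. Intersomatic distances are computed in the 2-D slice plane (depth
excluded), matching how they are measured from micrographs; whether original
measurements of this kind are 2-D or 3-D is generally unstated, and the 2-D
convention is an explicit assumption here.

## The synthetic generator

The generator emulates the experimental designs the analysis stages consume.
It is phenomenological by intent: the quantity under test is always the
*analysis*, not a biophysical circuit model.

- **Membrane.** A single-compartment RC membrane (R_m = 200 MΩ,
  C_m = 100 pF, τ = 20 ms, rest −50 mV) with threshold-reset spiking
  (threshold −35 mV, reset −45 mV, 2 ms refractoriness) and stereotyped 1 ms
  spike waveforms. Subthreshold responses follow
  V = V_rest + I·R_m·(1 − e^(−t/τ)) exactly (exponential-Euler update).
- **Synaptic kernel.** All PSCs/PSPs are difference-of-two-exponentials
  waveforms, peak-normalised so that an event's "amplitude" equals its peak.
  Defaults: PSP rise 2 ms / decay 20 ms; PSC rise 0.5 ms / decay 6 ms.
- **Screening sessions.** 4 cells (quadruple configuration), 5 imposed spikes
  at 50 Hz starting at 100 ms, 1 ms synaptic delay, Gaussian noise
  sd 0.25 mV, PSP amplitude 0.5 mV for connected pairs. Somata are scattered
  over a 150 µm field; depths 12–123 µm.
- **sPSC barrages.** Homogeneous Poisson events at 3 Hz (the spontaneous
  event *rate* is not constrained by published values and is a free
  parameter; 3 Hz is a typical slice figure). Amplitudes are log-normal with
  median 16.9 pA and log-sd 0.605, chosen so the population mean and sd are
  ≈ 20.3 and 13.5 pA — the published scale of spontaneous currents in this
  preparation. The heavy right tail is deliberate: it is what makes a
  "top-5 %" statistic meaningful.
- **Optogenetic trials.** Each light pulse evokes, per connected source, one
  PSC at latency ~ N(6, 1) ms (within the published 2.4–11.5 ms monosynaptic
  range), with amplitude drawn from the *same* log-normal law as the sPSCs —
  the modelling premise behind the ratio estimator is precisely that each
  connected source behaves like one spontaneous-release site. With
  probability 0.1 a source fires a doublet 3–8 ms later, producing a
  compound multiphasic oPSC. Optionally a simultaneously recorded opsin+
  cell carries brief −500 pA runaway action currents, so detectors can be
  stress-tested against clamp artifacts.
- **Light ramps.** 2 s baseline, 5 s linear 0→1 intensity ramp. The
  oscillatory (cortex-like) condition adds an amplitude-modulated narrowband
  current — envelope growing linearly with intensity to 20 pA, frequency
  40 ± 2 Hz inside the 10–80 Hz band, random phase; the silent (LH-like)
  condition adds only a 30 pA tonic inward ramp with unchanged sPSC
  statistics. The oscillation is generated phenomenologically rather than by
  an explicit E/I network because the analysis under test is spectral
  detection, not network mechanism.
- **Randomness.** One global seed; each component derives an independent
  substream as `default_rng([seed, fixed_offset, index…])`, so sessions are
  bit-reproducible and components can be re-drawn independently.

What the generator does *not* emulate — electrode drift, access-resistance
changes, temperature effects, short-term plasticity across the 5-spike
train, dendritic filtering, correlated (non-Poisson) spontaneous activity —
bounds what passing tests show: they demonstrate calibrated behaviour of the
analysis under the stated noise model, not robustness to every property of
real recordings.

## Screening detection rule and its calibration

Published screens of this kind report verdicts, not the criterion; the rule
here is explicit and calibrated. The trial-averaged follower trace is
smoothed with a 2 ms boxcar; baseline sd is taken from the pre-train segment
of that smoothed average. For each presynaptic spike the local baseline is
the mean over [−2.5, −0.5] ms before the spike; responses are the
deflections in a 1–20 ms post-spike window; the detection statistic is the
peak of the spike-triggered *average* deflection. Detection requires that
peak to exceed `k_sd = 3` baseline sd *and* per-spike polarity agreement on
≥ 60 % of spikes. Latency is spike-to-10 %-of-peak crossing.

Monte-Carlo calibration on null sessions (no connections, 20 trials) gives
an empirical false-positive rate of ~0/1200 directed tests — conservative
against a nominal α of 0.05 — while sensitivity at PSP amplitudes ≥ 5× the
averaged-trace noise sd is complete, with detection probability monotone in
amplitude. Two systematic effects are documented rather than corrected: the
2 ms smoothing attenuates sharp PSP peaks by a few percent, and for 50 Hz
trains whose PSP decay (20 ms) spans the inter-spike interval, later
responses ride the preceding decay, so the reported evoked amplitude
underestimates the true PSP peak by roughly 15–20 %. Detection calls are
unaffected (the bias shrinks amplitudes, never inflates them). PSP polarity
is *not* used to classify transmitter identity — holding potentials differ
across experiments, so classification would require explicit
holding-potential metadata.

## Coupling coefficient

`c = ΔV_post / ΔV_pre`, both measured as the mean over the last 20 % of the
step minus the pre-step baseline mean; presynaptic deflections below 1 mV
flag the estimate unreliable instead of returning a number. A pair is
"coupled" when both directional coefficients exceed 0.005 — below the noise
floor of typical ΔV estimates, and requiring bidirectionality, the
gap-junction phenotype. Recovery on simulated coefficients 0.01–0.1 is
within a few percent provided the presynaptic deflection is well resolved;
with small steps and few sweeps the c = 0.01 case becomes noise-limited
(ΔV_post ≈ 0.1 mV against 0.25 mV noise), which is why the recovery suites
use −100 pA steps and ~10 step sweeps.

## Event detection

A sliding least-squares fit of the template (free scale and offset) is
computed at every sample via FFT correlations; the detection statistic is
fitted scale / its standard error, thresholded at 4 with an equal prominence
requirement and a 5 ms minimum peak separation. Fitted amplitudes below
2 pA are discarded (a minimum-amplitude cutoff is standard practice; the
original cutoff of such analyses is typically unreported). The identical
template, threshold and alignment serve spontaneous and light-evoked events;
classification into sPSC/oPSC happens afterwards purely from light-pulse
times (onset inside [light + 1 ms, light + 20 ms), a window bounding the
published monosynaptic latency range).

Compound (multiphasic) events are recognised by a residual test: the fitted
template is subtracted and the matched filter re-run within the separation
limit; a surviving second component marks the event compound. Compound
events contribute their full baseline-to-peak amplitude (they were evoked by
multiplet firing and their charge genuinely reaches the cell) but their
rise/decay kinetics are withheld as unreliable. Onset is the 10 %-of-peak
crossing; rise time is 20–80 %; decay τ is a log-linear single-exponential
fit from the 90 %-of-peak point down to 20 %, requiring the snippet to
contain the decay to ≤ 20 % of peak.

Calibration: on pure noise the detector fires < 0.1 events/s; amplitude
recovery bias at SNR ≥ 5 is within 5 % (the fitted scale, not the noisy
extremum, is the amplitude estimate for simple events).

## The oPSC/sPSC ratio as a presynaptic-count estimator

Per cell: mean sPSC amplitude, the mean of the ⌈0.05·n⌉ largest sPSCs
(top-5 %; ceiling keeps the set non-empty for small n, while a ≥ 20-event
precondition gates reliability), mean oPSC amplitude, and
ratio = mean oPSC / mean sPSC. The estimated presynaptic count is the ratio
rounded half-up, floored at 1 whenever any oPSC was detected (a detected
response implies at least one source). Under the generator's premise —
sources drawn from the sPSC law, amplitudes superposing linearly — the
estimate recovers 1, 2, 3 and 5 sources within ±1 in ≈ 100 % of seeded runs
at 50 light trials. Small biases partially cancel: latency jitter spreads
component peaks (lowering compound peaks below the arithmetic sum), while
multiplets and spontaneous events falling inside light windows add charge.

## Spectral analysis

Sweeps are high-pass filtered with a zero-phase 4th-order Butterworth at
10 Hz (zero-phase preserves event timing), then short-time PSDs are computed
with Hann-tapered 0.5 s windows at 95 % overlap (181 windows tile a 5 s
sweep). Band power integrates the PSD trapezoidally over bins in the
half-open band [10, 80) Hz; with density scaling this makes a pure tone of
amplitude A read A²/2 — band powers are signal variance in the band, in pA².
The density normalisation and the Hann taper are explicit choices where
common practice leaves them unstated. The per-cell "increase" is mean band
power over the full ramp minus mean band power over the 1 s immediately
preceding ramp onset (both intervals configurable).

Across 100 seeded single-cell sessions, oscillatory and silent conditions
separate with (typically) zero overlap, and rerunning the same cells with
the oscillation off — the in-silico analogue of synaptic blockade — removes
≈ 98–99 % of the band-power increase. One fragility is documented: the
log-normal amplitude law occasionally (≈ 1 % of sessions) produces a giant
spontaneous event (hundreds of pA) whose broadband power rivals a 20 pA
oscillation envelope, so a rare silent-condition session can reach the
oscillatory minimum. This is a property of heavy-tailed spontaneous
activity, not of the spectral estimator.

## Statistics and reporting

Group values are reported as mean ± sd. Comparisons are two-sided: paired or
unpaired t tests, Wilcoxon rank-sum (exact p for group sizes ≤ 25, normal
approximation above — fixture-scale results reproduce to the digit), or
Wilcoxon signed-rank. No multiple-testing correction is applied: the
screening design yields a handful of planned comparisons, not an exploratory
family. Rate tables use exact Clopper–Pearson intervals because the regime
of interest is counts at or near zero, where Wald intervals are useless.
Directed chemical tests (two per simultaneously probed pair) and undirected
coupling pairs are kept distinct throughout.

## Problem sizes

Default suites use quadruple (4-cell) sessions with 20 screening trials,
50-pulse optogenetic trials, single-cell 7.5 s ramp sweeps at 10 kHz, and
100-run calibration loops; these sizes give stable Monte-Carlo estimates
(binomial se ≈ 1–3 % at the calibrated rates) while a full test-plus-
acceptance cycle completes in about a minute on one CPU.

## Known limitations

- The screening amplitude underestimates true PSP size for fast trains
  (documented above); no deconvolution is attempted.
- Compound oPSCs are not decomposed into their components; multi-template
  classification and quantal analysis are out of scope.
- The ramp oscillation is stationary in frequency (±2 Hz per cell); real
  induced rhythms drift.
- Sessions are stored in the package's own HDF5 layout; vendor amplifier
  formats are not read, and NWB export is not provided.
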