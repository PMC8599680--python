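# Methods

## The measurement this package models

Visually evoked fields (VEFs) are the magnetic counterpart of visual evoked
potentials: after a flash or a checkerboard contrast reversal, the occipital
cortex produces a stereotyped sequence of field deflections — an early P1,
a main P2 (P100 for pattern reversal), and a late P3 — measurable with
femtotesla-class magnetometers. Two sensor placements matter here: Oz over
the primary visual cortex (V1) and POz over the associative visual cortex
(V2). Wearable optically-pumped magnetometers (OPMs) sit ~5 mm from the
scalp and record two field axes (tangential *y*, radial *z*) at 1 kHz;
SQUID systems sit ~50 mm away in a fixed dewar and record the radial axis
at 2 kHz. Because the field of a compact cortical source falls off as a
power law in distance, the near sensor sees a larger signal for the same
source, and that amplitude advantage converts directly into finer *temporal*
resolution (below).

## Temporal resolution model

For a Gaussian pulse g(t) = A·exp(−(t−t₀)²/(2σ²)) whose trial-averaged
trace carries a time-independent standard error ε, the time after (or
before) the peak at which the signal is distinguishable from the peak value
— i.e. lower by ε — is

    t_res = σ · sqrt(−2 ln(1 − ε/A)),        valid for ε/A < 1,

with the first-order (small ε/A) form t_res ≈ σ·sqrt(2ε/A). The scaling
t_res ∝ w / sqrt(SnR), with SnR = A/ε, carries over to non-Gaussian pulses
of width w. Since evoked components rarely admit clean functional fits, the
pipeline characterizes pulses non-parametrically:

- **width w** — the time between the two strict local minima adjacent to the
  peak (for a negative-going pulse the trace is sign-flipped first, so the
  "minima" are the flanking positive peaks);
- **amplitude A** — peak value minus the mean of the two minima values;
- **figure of merit η = √A / w** — larger η means finer temporal
  resolution.

The empirical time error of a peak is read off the standard-error band: the
full two-sided span around the peak over which the mean trace stays within
ε(t_peak) of the peak value, with crossing times interpolated linearly
between samples. For a Gaussian pulse under constant ε this span equals
2·t_res exactly, which is the package's closed-form closure test. Whether
the "time error" should be this full span or its half is ambiguous in
general usage; this package consistently uses the full span for a feature's
`delta_t_ms` and half-spans (per site) when combining independent
uncertainties.

Uncertainty propagation for η is first order with A and w independent:
δη = η·sqrt((δA/2A)² + (δw/w)²), where δA is the standard error at the
peak and δw combines the half band-spans at the two bracketing minima in
quadrature. A Monte-Carlo test confirms the linearization to 5% for
relative input errors up to ~6%.

### Numerical conventions for extrema

Local minima on the sampled grid are strict sign changes of the first
difference; a plateau of equal samples counts once, at its midpoint;
endpoints never qualify. If a side of a peak has no strict minimum (e.g. a
monotone tail), the epoch edge is used and the feature is flagged
`edge_truncated`. Peak search inside a component window takes the sample of
largest absolute value; the minima search then runs over the full epoch, so
bracketing minima may legitimately lie outside the window. No smoothing is
applied before extrema detection.

### Sensitivity of the band-crossing estimator

The band span assumes the averaged trace is locally smooth near the
crossing. That holds for band-limited data — which is what the 5–60 Hz
filtered pipeline produces — and there the span closes with 2·t_res within
one sample across seeds. On traces carrying raw sample-to-sample (white)
roughness comparable to ε, the first crossing is hit early and the span is
biased low; the estimator is therefore only meaningful downstream of the
band-pass, where the pipeline applies it.

## Pipeline stages and their parameters

**Filtering.** 4th-order Butterworth band-pass 5–60 Hz plus band-stop
49–51 Hz (mains), each applied forward-and-backward (`sosfiltfilt`) on the
*continuous* record. Zero phase is non-negotiable: latencies are the
pipeline's product, and any causal filter's group delay would bias them.
Filtering before epoching keeps edge transients out of trials; a 1 s guard
band at either end of the record is excluded from epoching in the pipeline
(the `epoch` function itself defaults to no guard so that its counting
behaviour is transparent). One documented side effect: the 5 Hz high-pass
reshapes overlapping slow components, shifting noiseless absolute peak
times by up to ~2 ms; because the shift is common to both sites, inter-site
delays are unaffected.

**Epoching.** Stimulus onset maps to the nearest sample (time 0); windows
are −45…350 ms for flash and 0…250 ms for pattern reversal; onsets whose
window leaves the recording are dropped and counted.

**Trial rejection.** "Interrupted" trials are operationalized as: any
non-finite sample, any constant segment ≥ 50 ms, or any sample beyond
10 pT in magnitude (far above physiological fields). Each removal is logged
by reason; rejecting every trial is an error.

**Averaging.** Mean across kept trials per time point; uncertainty is the
standard error of that mean. No baseline correction by default (an optional
pre-stimulus-mean flag exists for flash epochs, which include −45 ms of
pre-stimulus data).

**Component selection.** Peak-latency windows default to the clinical
literature: P1 35–60 ms, P2 83–152 ms, P3 160–230 ms. Within a window,
every local extremum is characterized and the one with the largest
characterized amplitude A wins — "dominant" by pulse size rather than raw
value, so baseline offsets cannot decide; ties break toward the earlier
latency. Windows with no extremum report the component absent.

**Delays.** Δτ = t_peak(Oz) − t_peak(POz) per component; positive Δτ means
the associative cortex led. Site uncertainties (half band-spans) combine in
quadrature, assuming independence between sensors.

**Planar magnitude.** |B_yz| = sqrt(B_y² + B_z²) pointwise; its standard
error follows by first-order propagation. The magnitude is insensitive to
in-plane field rotation, which can otherwise masquerade as an amplitude
change on a single axis and distort single-axis peak times. Planar traces
are non-negative, so their characterization never needs the sign-flip
branch.

**Reproducibility.** Pearson correlation between averaged evoked traces
over the full epoch (range configurable). Within-participant tables report
the mean of all pairwise run correlations with the standard error of that
mean (the collapse rule is a package choice; several are defensible).
Between-participant tables correlate participant-averaged traces and quote
a 95% CI half-width via the Fisher z-transform. The two uncertainty kinds
are tagged explicitly.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
cortical physiology:

- **Stimulus schedules.** Flash: 0.08 s flashes, each followed by a dark
  period drawn uniformly over whole 60 Hz projector frames between 0.92 and
  1.00 s; 300 s per run (~280–300 trials). Note the frame grid and the
  seconds bounds are mutually inconsistent at the lower edge (55 frames =
  0.9167 s < 0.92 s); the generator honours the seconds bounds, giving
  56–60 frames. Pattern reversal: reversals every 0.5 s, 280 s runs.
- **Evoked model.** Each component is a Gaussian pulse per site and axis.
  Defaults: P1 +200 fT at 50 ms (σ = 8 ms), P2 −480 fT at 120 ms
  (σ = 15 ms), P3 +300 fT at 190 ms (σ = 15 ms) on the radial axis at Oz;
  the tangential axis carries 0.4× and POz 0.85× of those amplitudes.
  Polarities alternate so the main trough is bracketed by the flanking
  peaks, as in measured bipolar VEFs. POz leads Oz by 10 ms (P2) and 20 ms
  (P3) by default — the order of magnitude reported for V2→V1 timing — and
  every latency jitters trial-to-trial with SD 3 ms, shared across sites
  and axes (the cortical event moves as one).
- **Sensor model.** White Gaussian noise at a flat 15 fT/√Hz density
  (RMS = density·sqrt(f_s/2)), plus a 50 Hz sinusoid (default 30 fT) with
  random phase per channel. No 1/f term: only a flat sensitivity figure is
  modelled. Evoked amplitudes are quoted at the 5 mm reference stand-off
  and scale as (5 mm / standoff)^p with p = 2 by default (current-dipole
  far-field heuristic); OPMs default to 5 mm/1 kHz/dual-axis, SQUIDs to
  50 mm/2 kHz/radial-only.
- **Determinism.** A single `numpy` generator seeded from the config drives
  schedule, jitter, noise and phase draws in a fixed order; identical
  configs give bit-identical recordings.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: non-Gaussian component shapes, amplitude
(not just latency) trial variability, correlated sensor noise, movement and
physiological artifacts, 1/f drift, head geometry, or any realistic forward
solution. SQUID gradiometry is reduced to a scalar stand-off amplitude
scaling. Parameter-recovery results certify the estimators under the
model's assumptions, nothing more.

## Study sizes used by tests and the acceptance script

The delay-recovery study uses 50 dual-site 300 s flash runs with programmed
POz leads drawn uniformly from 5–30 ms and OPM-like noise; the late-window
is opened a priori to (153, 230) ms because a 30 ms lead places the POz
late component at 160 ms — the edge of the literature window — and the
analysis window must contain every programmed latency for the recovery
question to be well-posed. Recovery achieves ~1 ms mean absolute error with
correct sign and near-complete coverage of the ±δ intervals.

The modality comparison scales the common source by 26.25 so that the far
(SQUID) sensor sees the main component near measured amplitudes
(~126 fT); with the default p = 2 power law over 5 mm vs 50 mm the near
sensor's signal is then far stronger and its η wins in every realization.
The asserted property is the *direction* of the advantage only — with p = 2
and a 10× distance ratio the simulated factor (~5–9×) is necessarily larger
than what mixed gradiometer/magnetometer hardware shows in practice.

## Known limitations

- Peak times are grid-quantized (1 ms OPM, 0.5 ms SQUID); no sub-sample
  peak interpolation is attempted, because the non-parametric width/
  amplitude definitions are grid-based too.
- The band-crossing time error requires SnR > 1 at the feature; features in
  noise-dominated traces come back edge-truncated or degenerate rather than
  silently wrong, but they are not meaningful.
- The curl-free reconstruction of the third field component from spatial
  gradients is out of scope: a two-sensor system provides no gradients.
- Correlation uncertainties use large-sample formulas; for the short
  correlation vectors of heavily cropped epochs they are approximate.
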