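# opmvef

Spatio-temporal analysis of visually evoked magnetic fields (VEFs) recorded
by scalp magnetometers — wearable optically-pumped magnetometers (OPMs)
over the primary (Oz) and associative (POz) visual cortex, with SQUID
systems as the far-stand-off reference.

The package is for researchers who want to quantify, from stimulus-locked
magnetometer traces, *when* evoked components occur and *how precisely*
that timing can be resolved: it takes raw multichannel recordings with a
trigger channel (or generates realistic synthetic ones), filters and epochs
them, averages trials with per-timepoint standard-error bands, and turns
the averages into component latencies, temporal-resolution figures of
merit, inter-site delays and reproducibility statistics.

## The model

For a Gaussian pulse g(t) = A·exp(−(t−t₀)²/(2σ²)) whose averaged trace
carries a standard error ε, the temporal resolution — the interval after
the peak before the signal differs from its peak value by ε — is

    t_res = σ √(−2 ln(1 − ε/A)) ≈ σ √(2ε/A),   valid for SnR = A/ε > 1,

i.e. t_res ∝ w / √SnR for general pulses of width w. Since evoked
components resist functional fits, pulses are characterized
non-parametrically: **w** is the time between the two local minima adjacent
to the peak, **A** the difference between the peak and the mean of those
minima, and the figure of merit is

    η = √A / w        [√fT / ms],

larger η meaning finer time resolution. Because field amplitude decays as a
power law in sensor stand-off, a near sensor (OPM, ~5 mm) achieves a higher
η than a far one (SQUID, ~50 mm) for the same source. Per-component
inter-site delays are Δτ = t_peak(Oz) − t_peak(POz) (positive: POz leads),
with uncertainties read off the standard-error bands. Dual-axis OPM data
additionally yield the planar magnitude |B_yz| = √(B_y² + B_z²), which is
immune to in-plane field rotation masquerading as amplitude change.

See `docs/methods.md` for the full method description, parameter defaults
and limitations.

## Worked example

```python
import opmvef as o

# default study: four 300 s flash runs, dual-axis OPMs at Oz and POz
bundle = o.run_pipeline(o.PipelineConfig(seed=1))

p2 = bundle["features"]["Oz_z"]["P2"]
print(f"P2 (Oz, radial): t_peak = {p2.t_peak_ms:.0f} ms, "
      f"A = {p2.amplitude_ft:.0f} fT, w = {p2.width_ms:.0f} ms, "
      f"eta = {p2.eta:.3f} ± {p2.delta_eta:.3f} sqrt(fT)/ms")
for comp in ("P2", "P3"):
    d = bundle["delays"][comp]
    print(f"{comp}: delta_tau = {d.delta_tau_ms:.0f} ± {d.delta_ms:.1f} ms")
```

prints

```
P2 (Oz, radial): t_peak = 121 ms, A = 517 fT, w = 107 ms, eta = 0.212 ± 0.046 sqrt(fT)/ms
P2: delta_tau = 11 ± 2.5 ms
P3: delta_tau = 19 ± 3.2 ms
```

The main component peaks ~120 ms post-flash with an amplitude around
500 fT; the associative-cortex site leads the primary site by ~10 ms for
the main component and ~20 ms for the late one (the simulator programs 10
and 20 ms; both recoveries land within the quoted uncertainty). The same
pipeline is scriptable from the shell:

```sh
opmvef simulate --seed 1 --out run.tsv
opmvef preprocess --in run.tsv --protocol flash --out evoked/
opmvef resolve --evoked evoked/evoked_Oz_z.h5 --window 83 152 --out p2.json
opmvef delays --oz evoked/evoked_Oz_z.h5 --poz evoked/evoked_POz_z.h5 --out delays.json
opmvef run-all --seed 1 --out results/
```

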