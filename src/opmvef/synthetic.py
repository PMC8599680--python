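"""Synthetic two-site, dual-axis magnetometer recordings of visually evoked fields.

The generator emulates the measurement setup the analysis pipeline expects:
two sensors over the visual cortex (Oz above V1, POz above V2), each
measuring one or two field axes (``y`` tangential, ``z`` radial), driven by a
flash or pattern-reversal stimulus schedule. Every evoked component is a
Gaussian pulse A·exp(−(t−t0)²/(2σ²)) with site-specific latency and signed
amplitude; sensor noise is white Gaussian at a flat spectral density plus a
50 Hz mains sinusoid; moving a sensor away from the scalp scales all evoked
amplitudes by a power law in the stand-off distance.

Runs are bit-reproducible: the same :class:`SyntheticConfig` (including its
seed) always produces the identical :class:`RawRecording`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SITES",
    "AXES",
    "StimulusSchedule",
    "ComponentSpec",
    "SensorSpec",
    "RawRecording",
    "SyntheticConfig",
    "default_components",
    "opm_sensor",
    "squid_sensor",
    "generate_flash_schedule",
    "generate_pr_schedule",
    "synthesize_evoked_waveform",
    "simulate_run",
]

logger = logging.getLogger(__name__)

SITES = ("Oz", "POz")
AXES = ("y", "z")

#: Scalp-to-sensor distance (mm) at which component amplitudes are quoted.
REFERENCE_STANDOFF_MM = 5.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSchedule:
    """Event times of one stimulation run.

    ``onsets`` are stimulus onset times in seconds, strictly increasing.
    ``event_duration`` is the flash length for the flash protocol and None
    for pattern reversal (a reversal is instantaneous).
    """

    protocol: str                 # "flash" | "pattern_reversal"
    onsets: np.ndarray            # s
    run_duration: float           # s
    frame_rate: float             # Hz
    event_duration: float | None = None  # s, flash only

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "onsets": [float(t) for t in self.onsets],
            "run_duration": self.run_duration,
            "frame_rate": self.frame_rate,
            "event_duration": self.event_duration,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusSchedule":
        return cls(
            protocol=d["protocol"],
            onsets=np.asarray(d["onsets"], dtype=float),
            run_duration=float(d["run_duration"]),
            frame_rate=float(d["frame_rate"]),
            event_duration=d.get("event_duration"),
        )


@dataclass(frozen=True)
class ComponentSpec:
    """One evoked component: a Gaussian pulse per site and axis.

    ``latency_ms`` maps site -> peak time t0 (ms post-onset); ``amplitude_ft``
    maps site -> axis -> signed amplitude (fT) quoted at the reference
    stand-off; ``jitter_ms`` is the trial-to-trial latency jitter SD, shared
    across sites and axes within a trial (the cortical event moves as one).
    """

    name: str                                   # "P1" | "P2" | "P3"
    latency_ms: Mapping[str, float]
    sigma_ms: float
    amplitude_ft: Mapping[str, Mapping[str, float]]
    jitter_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_ms <= 0:
            raise ValueError(f"component {self.name}: sigma must be > 0")
        if self.jitter_ms < 0:
            raise ValueError(f"component {self.name}: jitter SD must be >= 0")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "latency_ms": dict(self.latency_ms),
            "sigma_ms": self.sigma_ms,
            "amplitude_ft": {s: dict(a) for s, a in self.amplitude_ft.items()},
            "jitter_ms": self.jitter_ms,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComponentSpec":
        return cls(
            name=d["name"],
            latency_ms=dict(d["latency_ms"]),
            sigma_ms=float(d["sigma_ms"]),
            amplitude_ft={s: dict(a) for s, a in d["amplitude_ft"].items()},
            jitter_ms=float(d.get("jitter_ms", 0.0)),
        )


@dataclass(frozen=True)
class SensorSpec:
    """One magnetometer: site, modality, measured axes, and noise model."""

    site: str
    modality: str = "OPM"                       # "OPM" | "SQUID"
    axes: tuple[str, ...] = ("y", "z")
    standoff_mm: float = 5.0
    noise_density: float = 15.0                 # fT/sqrt(Hz)
    sampling_rate: float = 1000.0               # Hz
    line_noise_amplitude: float = 30.0          # fT at 50 Hz

    def __post_init__(self) -> None:
        if self.standoff_mm <= 0:
            raise ValueError("standoff must be > 0")
        if self.noise_density < 0:
            raise ValueError("noise density must be >= 0")
        for ax in self.axes:
            if ax not in AXES:
                raise ValueError(f"unknown axis {ax!r}")

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "modality": self.modality,
            "axes": list(self.axes),
            "standoff_mm": self.standoff_mm,
            "noise_density": self.noise_density,
            "sampling_rate": self.sampling_rate,
            "line_noise_amplitude": self.line_noise_amplitude,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SensorSpec":
        return cls(
            site=d["site"],
            modality=d.get("modality", "OPM"),
            axes=tuple(d.get("axes", ("y", "z"))),
            standoff_mm=float(d.get("standoff_mm", 5.0)),
            noise_density=float(d.get("noise_density", 15.0)),
            sampling_rate=float(d.get("sampling_rate", 1000.0)),
            line_noise_amplitude=float(d.get("line_noise_amplitude", 30.0)),
        )


@dataclass
class RawRecording:
    """Continuous multichannel recording with a per-sample trigger channel.

    ``channels`` is [n_samples, n_channels] in fT; labels are ``<site>_<axis>``.
    The trigger is 1 at the sample nearest each stimulus onset, 0 elsewhere.
    """

    time: np.ndarray                  # s, uniform grid
    channels: np.ndarray              # fT
    channel_labels: list[str]
    trigger: np.ndarray               # int event codes
    sampling_rate: float              # Hz

    def __post_init__(self) -> None:
        if self.channels.ndim != 2:
            raise ValueError("channels must be 2-D [n_samples, n_channels]")
        if self.channels.shape[0] != self.time.shape[0]:
            raise ValueError("time and channels length mismatch")
        if self.channels.shape[1] != len(self.channel_labels):
            raise ValueError("channel label count mismatch")
        if self.trigger.shape[0] != self.time.shape[0]:
            raise ValueError("trigger length mismatch")

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.channels[:, self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channel_labels}") from None

    def onset_indices(self) -> np.ndarray:
        return np.flatnonzero(self.trigger != 0)


def default_components() -> tuple[ComponentSpec, ...]:
    """Default P1/P2/P3 triad for flash stimulation.

    Latencies sit inside the literature windows (P1 35-60, P2 83-152,
    P3 160-230 ms); polarities alternate (+, -, +) so the main P2 trough is
    bracketed by the P1 and P3 peaks, as in measured bipolar evoked fields.
    POz leads Oz by 10 ms for P2 and 20 ms for P3 (the Oz response is the
    delayed one), matching the order of magnitude of reported inter-site
    delays. Amplitudes are quoted at the 5 mm reference stand-off; the
    tangential y axis carries a weaker copy of the radial z response.
    """
    def site_amp(a_oz: float) -> dict[str, dict[str, float]]:
        out = {}
        for site, s in (("Oz", 1.0), ("POz", 0.85)):
            out[site] = {"y": 0.4 * a_oz * s, "z": a_oz * s}
        return out

    return (
        ComponentSpec("P1", {"Oz": 50.0, "POz": 50.0}, 8.0, site_amp(+200.0), 3.0),
        ComponentSpec("P2", {"Oz": 120.0, "POz": 110.0}, 15.0, site_amp(-480.0), 3.0),
        ComponentSpec("P3", {"Oz": 190.0, "POz": 170.0}, 15.0, site_amp(+300.0), 3.0),
    )


def opm_sensor(site: str, **overrides) -> SensorSpec:
    """Wearable OPM: 5 mm stand-off, dual-axis, 1 kHz."""
    kw = dict(modality="OPM", axes=("y", "z"), standoff_mm=5.0,
              noise_density=15.0, sampling_rate=1000.0)
    kw.update(overrides)
    return SensorSpec(site, **kw)


def squid_sensor(site: str, **overrides) -> SensorSpec:
    """In-dewar SQUID: 50 mm stand-off, radial axis only, 2 kHz."""
    kw = dict(modality="SQUID", axes=("z",), standoff_mm=50.0,
              noise_density=15.0, sampling_rate=2000.0)
    kw.update(overrides)
    return SensorSpec(site, **kw)


@dataclass(frozen=True)
class SyntheticConfig:
    """Complete generative description of one measurement run.

    Serializable; together with ``seed`` it reproduces a run bit-exactly.
    Defaults follow the flash protocol: 0.08 s flashes separated by a dark
    period drawn uniformly on the 60 Hz frame grid between 0.92 and 1.00 s,
    300 s per run, recorded by dual-axis OPMs at Oz and POz.
    """

    protocol: str = "flash"
    run_duration: float = 300.0        # s
    flash_len: float = 0.08            # s
    isi_min: float = 0.92              # s
    isi_max: float = 1.00              # s
    reversal_interval: float = 0.5     # s
    frame_rate: float = 60.0           # Hz
    components: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    sensors: tuple[SensorSpec, ...] = (
        SensorSpec("Oz"), SensorSpec("POz"))
    standoff_exponent: float = 2.0     # amplitude ~ (ref/standoff)^p
    reference_standoff_mm: float = REFERENCE_STANDOFF_MM
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {s.sampling_rate for s in self.sensors}
        if len(rates) > 1:
            raise ValueError(
                "all sensors in one run must share a sampling rate; "
                "simulate OPM and SQUID sessions as separate runs")
        for comp in self.components:
            for sensor in self.sensors:
                if sensor.site not in comp.latency_ms:
                    raise ValueError(
                        f"component {comp.name} has no latency for site {sensor.site}")
                for ax in sensor.axes:
                    if ax not in comp.amplitude_ft.get(sensor.site, {}):
                        raise ValueError(
                            f"component {comp.name} has no amplitude for "
                            f"{sensor.site}_{ax}")

    @property
    def sampling_rate(self) -> float:
        return self.sensors[0].sampling_rate

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "run_duration": self.run_duration,
            "flash_len": self.flash_len,
            "isi_min": self.isi_min,
            "isi_max": self.isi_max,
            "reversal_interval": self.reversal_interval,
            "frame_rate": self.frame_rate,
            "components": [c.to_dict() for c in self.components],
            "sensors": [s.to_dict() for s in self.sensors],
            "standoff_exponent": self.standoff_exponent,
            "reference_standoff_mm": self.reference_standoff_mm,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        kw = dict(d)
        kw["components"] = tuple(
            ComponentSpec.from_dict(c) for c in d.get("components", ()))
        if not kw["components"]:
            kw.pop("components")
        kw["sensors"] = tuple(SensorSpec.from_dict(s) for s in d.get("sensors", ()))
        if not kw["sensors"]:
            kw.pop("sensors")
        return cls(**kw)


# ---------------------------------------------------------------------------
# Stimulus schedules
# ---------------------------------------------------------------------------

def generate_flash_schedule(
    run_duration: float,
    flash_len: float = 0.08,
    isi_min: float = 0.92,
    isi_max: float = 1.00,
    frame_rate: float = 60.0,
    seed: int | np.random.Generator = 0,
) -> StimulusSchedule:
    """Flash protocol: brief flashes separated by pseudo-random dark periods.

    The dark period after each flash is drawn uniformly over whole projector
    frames between ``isi_min`` and ``isi_max`` (0.92-1.00 s is 55-60 frames
    at 60 Hz), so the inter-onset gap is ``flash_len`` plus the drawn ISI.
    The first flash starts at t=0 and every flash fits inside the run.
    """
    if flash_len <= 0:
        raise ValueError("flash length must be > 0")
    if isi_min > isi_max:
        raise ValueError("isi_min must be <= isi_max")
    if run_duration < flash_len + isi_min:
        raise ValueError(
            f"run duration {run_duration} s too short for any flash cycle "
            f"({flash_len + isi_min} s)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # whole projector frames, kept inside [isi_min, isi_max]
    f_min = int(np.ceil(isi_min * frame_rate - 1e-9))
    f_max = int(np.floor(isi_max * frame_rate + 1e-9))
    if f_max < f_min:
        raise ValueError("no whole frame count lies between isi_min and isi_max")
    onsets = [0.0]
    while True:
        isi = rng.integers(f_min, f_max + 1) / frame_rate
        nxt = onsets[-1] + flash_len + isi
        if nxt + flash_len > run_duration:
            break
        onsets.append(nxt)
    return StimulusSchedule(
        protocol="flash",
        onsets=np.asarray(onsets),
        run_duration=run_duration,
        frame_rate=frame_rate,
        event_duration=flash_len,
    )


def generate_pr_schedule(
    run_duration: float,
    interval: float = 0.5,
    post_margin: float = 0.0,
    frame_rate: float = 60.0,
) -> StimulusSchedule:
    """Pattern-reversal protocol: checkerboard inversions at fixed intervals.

    Onsets lie at 0, interval, 2·interval, ... strictly below
    ``run_duration − post_margin``; the margin reserves room for the
    post-stimulus epoch window so every reversal can be epoched.
    """
    if interval <= 0:
        raise ValueError("reversal interval must be > 0")
    if post_margin < 0:
        raise ValueError("post margin must be >= 0")
    limit = run_duration - post_margin
    n = int(np.ceil(limit / interval - 1e-12))
    if n < 1:
        n = 1  # a lone reversal at t=0 still constitutes an event
    onsets = np.arange(n) * interval
    return StimulusSchedule(
        protocol="pattern_reversal",
        onsets=onsets,
        run_duration=run_duration,
        frame_rate=frame_rate,
        event_duration=None,
    )


# ---------------------------------------------------------------------------
# Evoked waveform and full run synthesis
# ---------------------------------------------------------------------------

def synthesize_evoked_waveform(
    components: Sequence[ComponentSpec],
    time_ms: np.ndarray,
    site: str,
    axis: str,
    amplitude_scale: float = 1.0,
    latency_shift_ms: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Noise-free evoked trace: a sum of Gaussian pulses on ``time_ms``.

    ``latency_shift_ms`` optionally shifts individual components (used for
    per-trial jitter); ``amplitude_scale`` applies stand-off scaling.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    trace = np.zeros_like(time_ms)
    for comp in components:
        t0 = comp.latency_ms[site]
        if latency_shift_ms is not None:
            t0 = t0 + latency_shift_ms.get(comp.name, 0.0)
        a = comp.amplitude_ft[site][axis] * amplitude_scale
        trace += a * np.exp(-((time_ms - t0) ** 2) / (2.0 * comp.sigma_ms ** 2))
    return trace


def _make_schedule(config: SyntheticConfig, rng: np.random.Generator) -> StimulusSchedule:
    if config.protocol == "flash":
        return generate_flash_schedule(
            config.run_duration, config.flash_len, config.isi_min,
            config.isi_max, config.frame_rate, seed=rng)
    if config.protocol == "pattern_reversal":
        return generate_pr_schedule(
            config.run_duration, config.reversal_interval,
            frame_rate=config.frame_rate)
    raise ValueError(f"unknown protocol {config.protocol!r}")


def simulate_run(
    config: SyntheticConfig,
    schedule: StimulusSchedule | None = None,
) -> tuple[RawRecording, StimulusSchedule]:
    """Simulate one measurement run described by ``config``.

    Evoked pulses are placed at every stimulus onset with per-trial latency
    jitter shared across channels; each channel then receives white Gaussian
    noise of RMS ``noise_density·sqrt(fs/2)`` (flat density over the Nyquist
    band) and a 50 Hz sinusoid of the configured amplitude with a random
    phase per channel. Evoked amplitudes are scaled by
    ``(reference_standoff/standoff)^p`` per sensor.

    Returns the recording and the schedule that drove it.
    """
    rng = np.random.default_rng(config.seed)
    if schedule is None:
        schedule = _make_schedule(config, rng)
    fs = config.sampling_rate
    n = int(round(config.run_duration * fs))
    time = np.arange(n) / fs

    trigger = np.zeros(n, dtype=np.int64)
    onset_idx = np.round(schedule.onsets * fs).astype(int)
    onset_idx = onset_idx[onset_idx < n]
    trigger[onset_idx] = 1

    n_trials = onset_idx.size
    # one jitter draw per component per trial, shared across sites and axes
    jitters = {
        comp.name: (rng.normal(0.0, comp.jitter_ms, n_trials)
                    if comp.jitter_ms > 0 else np.zeros(n_trials))
        for comp in config.components
    }

    labels: list[str] = []
    columns: list[np.ndarray] = []
    for sensor in config.sensors:
        scale = (config.reference_standoff_mm / sensor.standoff_mm) ** config.standoff_exponent
        for axis in sensor.axes:
            sig = np.zeros(n)
            for comp in config.components:
                a = comp.amplitude_ft[sensor.site][axis] * scale
                sigma_s = comp.sigma_ms / 1000.0
                # +-9 sigma keeps the truncated tail below 1e-15 of the peak
                half = int(round(9 * sigma_s * fs))
                jit = jitters[comp.name]
                for k, i0 in enumerate(onset_idx):
                    t0 = time[i0] + (comp.latency_ms[sensor.site] + jit[k]) / 1000.0
                    lo = max(0, int(round(t0 * fs)) - half)
                    hi = min(n, int(round(t0 * fs)) + half + 1)
                    if lo >= hi:
                        continue
                    tt = time[lo:hi] - t0
                    sig[lo:hi] += a * np.exp(-(tt ** 2) / (2.0 * sigma_s ** 2))
            if sensor.noise_density > 0:
                sig = sig + rng.normal(
                    0.0, sensor.noise_density * np.sqrt(fs / 2.0), n)
            if sensor.line_noise_amplitude > 0:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                sig = sig + sensor.line_noise_amplitude * np.sin(
                    2.0 * np.pi * 50.0 * time + phase)
            labels.append(f"{sensor.site}_{axis}")
            columns.append(sig)

    rec = RawRecording(
        time=time,
        channels=np.column_stack(columns),
        channel_labels=labels,
        trigger=trigger,
        sampling_rate=fs,
    )
    logger.info("simulated %s run: %d events, %d channels, %.0f s at %g Hz",
                schedule.protocol, n_trials, len(labels),
                config.run_duration, fs)
    return rec, schedule
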