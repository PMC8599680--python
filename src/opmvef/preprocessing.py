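"""Filtering, epoching, trial rejection and time-locked averaging.

The pipeline's product is peak *latencies*, so every filter here is applied
forward-and-backward (zero phase): a causal filter's group delay would bias
each latency and the inter-site delays built on them. Filtering happens on
the continuous record, before epoching, so filter transients stay outside
the trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal

from .synthetic import RawRecording, StimulusSchedule

__all__ = [
    "FilterSpec",
    "EpochSet",
    "EvokedResponse",
    "apply_filters",
    "epoch",
    "reject_trials",
    "average_evoked",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass plus band-stop filter settings (Hz).

    Defaults isolate the evoked-field band (5-60 Hz) and notch out 50 Hz
    mains interference (49-51 Hz). ``order`` is the order of each underlying
    Butterworth prototype; the forward-backward pass doubles the effective
    order.
    """

    bandpass: tuple[float, float] = (5.0, 60.0)
    bandstop: tuple[float, float] | None = (49.0, 51.0)
    design: str = "zero_phase_iir"
    order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.bandpass
        if not 0 < lo < hi:
            raise ValueError("bandpass edges must satisfy 0 < low < high")
        if self.bandstop is not None:
            lo, hi = self.bandstop
            if not 0 < lo < hi:
                raise ValueError("bandstop edges must satisfy 0 < low < high")
        if self.design != "zero_phase_iir":
            raise ValueError(f"unknown filter design {self.design!r}")

    def to_dict(self) -> dict:
        return {
            "bandpass": list(self.bandpass),
            "bandstop": list(self.bandstop) if self.bandstop else None,
            "design": self.design,
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterSpec":
        return cls(
            bandpass=tuple(d.get("bandpass", (5.0, 60.0))),
            bandstop=tuple(d["bandstop"]) if d.get("bandstop") else None,
            design=d.get("design", "zero_phase_iir"),
            order=int(d.get("order", 4)),
        )


@dataclass
class EpochSet:
    """Stimulus-locked trials cut from one recording.

    ``trials`` is [n_trials, n_samples, n_channels] (fT); ``time_ms`` is the
    epoch grid relative to onset (0 at the onset sample). ``kept`` holds the
    original trial indices still present; ``rejected`` maps a reason to the
    original indices removed for it.
    """

    trials: np.ndarray
    time_ms: np.ndarray
    channel_labels: list[str]
    sampling_rate: float
    kept: list[int] = field(default_factory=list)
    rejected: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D [n_trials, n_samples, n_channels]")
        if not self.kept:
            self.kept = list(range(self.trials.shape[0]))

    @property
    def n_trials(self) -> int:
        return int(self.trials.shape[0])

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channel_labels}") from None


@dataclass
class EvokedResponse:
    """Trial-averaged trace with its per-timepoint standard-error band."""

    time_ms: np.ndarray
    mean: np.ndarray          # fT
    sem: np.ndarray           # fT, >= 0
    n_trials: int
    channel: str

    def __post_init__(self) -> None:
        if not (self.time_ms.shape == self.mean.shape == self.sem.shape):
            raise ValueError("time, mean and sem must share one grid")
        if np.any(self.sem < 0):
            raise ValueError("standard error must be non-negative")

    @property
    def sampling_rate(self) -> float:
        return 1000.0 / float(np.median(np.diff(self.time_ms)))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _design_sos(spec: FilterSpec, fs: float) -> list[np.ndarray]:
    nyq = fs / 2.0
    if spec.bandpass[1] >= nyq:
        raise ValueError(
            f"bandpass upper edge {spec.bandpass[1]} Hz >= Nyquist {nyq} Hz")
    sections = [signal.butter(spec.order, spec.bandpass, "bandpass",
                              fs=fs, output="sos")]
    if spec.bandstop is not None:
        if spec.bandstop[1] >= nyq:
            raise ValueError(
                f"bandstop upper edge {spec.bandstop[1]} Hz >= Nyquist {nyq} Hz")
        sections.append(signal.butter(spec.order, spec.bandstop, "bandstop",
                                      fs=fs, output="sos"))
    return sections


def apply_filters(raw: RawRecording, spec: FilterSpec = FilterSpec()) -> RawRecording:
    """Zero-phase band-pass + band-stop filtering of every data channel.

    Each Butterworth section runs forward and backward (``sosfiltfilt``), so
    passband components keep their timing exactly; the band-stop section
    suppresses 50 Hz interference; the band-pass removes DC and drifts.
    The trigger channel is passed through untouched.
    """
    out = raw.channels.astype(float, copy=True)
    for sos in _design_sos(spec, raw.sampling_rate):
        out = signal.sosfiltfilt(sos, out, axis=0)
    return RawRecording(
        time=raw.time,
        channels=out,
        channel_labels=list(raw.channel_labels),
        trigger=raw.trigger,
        sampling_rate=raw.sampling_rate,
    )


def epoch(
    raw: RawRecording,
    schedule: StimulusSchedule,
    window_ms: tuple[float, float] = (-45.0, 350.0),
    guard_s: float = 0.0,
) -> EpochSet:
    """Cut one stimulus-locked trial per schedule onset.

    ``window_ms`` is (pre, post) relative to onset, e.g. (-45, 350) for the
    flash protocol and (0, 250) for pattern reversal. Onsets whose window
    leaves the recording — or the optional ``guard_s`` margin at either end,
    used to keep filter edge transients out of trials — are dropped and the
    count logged.
    """
    if schedule.n_events == 0:
        raise ValueError("cannot epoch an empty stimulus schedule")
    fs = raw.sampling_rate
    pre, post = window_ms
    if pre > post:
        raise ValueError("epoch window must satisfy pre <= post")
    off_lo = int(round(pre * fs / 1000.0))
    off_hi = int(round(post * fs / 1000.0))
    lo_bound = int(round(guard_s * fs))
    hi_bound = raw.n_samples - int(round(guard_s * fs))

    onset_idx = np.round(np.asarray(schedule.onsets) * fs).astype(int)
    trials = []
    dropped = 0
    for i0 in onset_idx:
        a, b = i0 + off_lo, i0 + off_hi
        if a < lo_bound or b >= hi_bound:
            dropped += 1
            continue
        trials.append(raw.channels[a:b + 1, :])
    if dropped:
        logger.info("epoching dropped %d/%d out-of-bounds onsets",
                    dropped, onset_idx.size)
    if not trials:
        raise ValueError("no onset fits inside the recording with this window")
    time_ms = np.arange(off_lo, off_hi + 1) / fs * 1000.0
    return EpochSet(
        trials=np.stack(trials),
        time_ms=time_ms,
        channel_labels=list(raw.channel_labels),
        sampling_rate=fs,
    )


def _max_flat_run(x: np.ndarray) -> int:
    """Longest run of consecutive equal samples in a 1-D trace (in samples)."""
    if x.size < 2:
        return x.size
    eq = np.diff(x) == 0
    if not eq.any():
        return 1
    # run lengths of consecutive True in eq; a run of m True = m+1 equal samples
    padded = np.concatenate(([False], eq, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    runs = edges[1::2] - edges[0::2]
    return int(runs.max()) + 1


def reject_trials(
    epochs: EpochSet,
    amplitude_ceiling: float = 10_000.0,
    flatline_ms: float = 50.0,
) -> EpochSet:
    """Remove trials with interrupted or saturated recordings.

    A trial goes if any channel contains (a) a non-finite sample, (b) a
    constant (flatlined) segment of at least ``flatline_ms``, or (c) a sample
    whose magnitude exceeds ``amplitude_ceiling`` (default 10 pT — far above
    any evoked field). Removal is logged per reason; rejecting everything is
    an error rather than an empty result.
    """
    flat_samples = flatline_ms * epochs.sampling_rate / 1000.0
    keep_mask = np.ones(epochs.n_trials, dtype=bool)
    reasons: dict[str, list[int]] = {"nonfinite": [], "flatline": [], "ceiling": []}
    for k in range(epochs.n_trials):
        trial = epochs.trials[k]
        orig = epochs.kept[k]
        if not np.isfinite(trial).all():
            reasons["nonfinite"].append(orig)
            keep_mask[k] = False
            continue
        if np.abs(trial).max() > amplitude_ceiling:
            reasons["ceiling"].append(orig)
            keep_mask[k] = False
            continue
        for ch in range(trial.shape[1]):
            # a run of m equal samples spans (m-1)/fs seconds
            if (_max_flat_run(trial[:, ch]) - 1) >= flat_samples:
                reasons["flatline"].append(orig)
                keep_mask[k] = False
                break
    if not keep_mask.any():
        raise ValueError("all trials rejected; nothing left to average")
    n_rej = int((~keep_mask).sum())
    if n_rej:
        logger.info("rejected %d/%d trials (%s)", n_rej, epochs.n_trials,
                    {k: len(v) for k, v in reasons.items() if v})
    merged = {k: sorted(set(epochs.rejected.get(k, [])) | set(v))
              for k, v in reasons.items()}
    merged = {k: v for k, v in merged.items() if v}
    for k, v in epochs.rejected.items():
        merged.setdefault(k, v)
    return EpochSet(
        trials=epochs.trials[keep_mask],
        time_ms=epochs.time_ms,
        channel_labels=list(epochs.channel_labels),
        sampling_rate=epochs.sampling_rate,
        kept=[i for i, m in zip(epochs.kept, keep_mask) if m],
        rejected=merged,
    )


def average_evoked(
    epochs: EpochSet,
    channel: str,
    baseline: bool = False,
) -> EvokedResponse:
    """Time-locked average of one channel with a standard-error band.

    The mean is taken across kept trials per time point; the uncertainty is
    the standard error of that mean, sd(trials)/sqrt(n). With ``baseline``
    the per-trial mean over the pre-stimulus samples (t < 0) is subtracted
    first — only meaningful for windows that include pre-stimulus data.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials to form a standard error")
    ci = epochs.channel_index(channel)
    data = epochs.trials[:, :, ci].astype(float)
    if baseline:
        pre = epochs.time_ms < 0
        if not pre.any():
            raise ValueError("baseline correction needs pre-stimulus samples")
        data = data - data[:, pre].mean(axis=1, keepdims=True)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sem = data.std(axis=0, ddof=1) / np.sqrt(n)
    return EvokedResponse(
        time_ms=epochs.time_ms.copy(),
        mean=mean,
        sem=sem,
        n_trials=n,
        channel=channel,
    )
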