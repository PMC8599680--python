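"""Shared fixtures: quiet (noise-free) simulator configs and evoked builders."""

from __future__ import annotations

import numpy as np
import pytest

from opmvef import (
    ComponentSpec,
    EvokedResponse,
    SensorSpec,
    SyntheticConfig,
    default_components,
)


def quiet_sensor(site: str, axes=("y", "z"), **kw) -> SensorSpec:
    """OPM-geometry sensor with all noise sources off."""
    kw.setdefault("noise_density", 0.0)
    kw.setdefault("line_noise_amplitude", 0.0)
    return SensorSpec(site, axes=axes, **kw)


def still_components() -> tuple[ComponentSpec, ...]:
    """Default component triad with trial-to-trial jitter removed."""
    return tuple(
        ComponentSpec(c.name, c.latency_ms, c.sigma_ms, c.amplitude_ft, 0.0)
        for c in default_components()
    )


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    """Short noiseless, jitter-free dual-site flash run."""
    return SyntheticConfig(
        run_duration=20.0,
        components=still_components(),
        sensors=(quiet_sensor("Oz"), quiet_sensor("POz")),
        seed=11,
    )


def make_evoked(mean, sem=None, dt_ms=1.0, t0_ms=0.0, n_trials=100,
                channel="Oz_z") -> EvokedResponse:
    """Wrap a plain array as an EvokedResponse on a uniform grid."""
    mean = np.asarray(mean, dtype=float)
    if sem is None:
        sem_arr = np.zeros_like(mean)
    elif np.isscalar(sem):
        sem_arr = np.full_like(mean, float(sem))
    else:
        sem_arr = np.asarray(sem, dtype=float)
    time_ms = t0_ms + np.arange(mean.size) * dt_ms
    return EvokedResponse(time_ms=time_ms, mean=mean, sem=sem_arr,
                          n_trials=n_trials, channel=channel)


def gaussian(time_ms, amplitude, t0_ms, sigma_ms):
    time_ms = np.asarray(time_ms, dtype=float)
    return amplitude * np.exp(-((time_ms - t0_ms) ** 2) / (2 * sigma_ms ** 2))
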