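"""Run-to-run and participant-to-participant reproducibility of evoked traces.

Consistency is quantified by the Pearson correlation between averaged evoked
waveforms. Within-participant tables report, per participant, the mean of
all pairwise run correlations with the standard error of that mean;
between-participant tables report pairwise correlations of
participant-averaged traces with a 95% confidence half-width (Fisher
z-transform). Anticorrelated traces between participants are a real
phenomenon (field polarity depends on individual cortical folding), so signs
are preserved throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import EvokedResponse

__all__ = ["CorrelationResult", "pearson_r", "correlation_table"]


@dataclass
class CorrelationResult:
    """A Pearson correlation with one tagged uncertainty."""

    r: float
    uncertainty: float
    uncertainty_kind: str      # "standard_error" | "ci95_halfwidth"
    n: int
    pair: str = ""

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be non-negative")


def _fisher_ci95_halfwidth(r: float, n: int) -> float:
    """Half-width of the 95% CI for r via the Fisher z-transform."""
    if n <= 3:
        raise ValueError("Fisher CI needs n > 3")
    if abs(r) >= 1.0:
        return 0.0
    z = math.atanh(r)
    h = 1.959963984540054 / math.sqrt(n - 3)
    return (math.tanh(z + h) - math.tanh(z - h)) / 2.0


def pearson_r(
    x: np.ndarray,
    y: np.ndarray,
    uncertainty: str = "standard_error",
    pair: str = "",
) -> CorrelationResult:
    """Pearson correlation of two traces with a tagged uncertainty.

    ``standard_error`` uses the large-sample form sqrt((1−r²)/(n−2));
    ``ci95_halfwidth`` uses the Fisher z-transform interval. Inputs must
    have equal length ≥ 3 and nonzero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("traces must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance trace")
    r = float(stats.pearsonr(x, y).statistic)
    r = max(-1.0, min(1.0, r))
    if uncertainty == "standard_error":
        u = math.sqrt(max(0.0, 1.0 - r * r) / (n - 2))
    elif uncertainty == "ci95_halfwidth":
        u = _fisher_ci95_halfwidth(r, n)
    else:
        raise ValueError(f"unknown uncertainty kind {uncertainty!r}")
    return CorrelationResult(r=r, uncertainty=u, uncertainty_kind=uncertainty,
                             n=n, pair=pair)


def _common_grid(traces: list[EvokedResponse]) -> np.ndarray:
    """Intersection of the epoch grids, keyed on times rounded to 1 ns."""
    keys = [np.round(ev.time_ms, 6) for ev in traces]
    common = keys[0]
    for k in keys[1:]:
        common = np.intersect1d(common, k)
    if common.size < 3:
        raise ValueError("evoked traces share no usable overlapping grid")
    return common


def _on_grid(ev: EvokedResponse, grid: np.ndarray) -> np.ndarray:
    key = np.round(ev.time_ms, 6)
    sel = np.isin(key, grid)
    return ev.mean[sel]


def correlation_table(
    traces: dict[str, list[EvokedResponse]],
    mode: str,
    time_range_ms: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Reproducibility table across runs ("within") or participants ("between").

    ``traces`` maps a participant label to that participant's per-run evoked
    traces. Within mode yields one row per participant: the mean pairwise
    Pearson r across the participant's runs, with the standard error of that
    mean. Between mode averages each participant's runs into one trace and
    yields one row per participant pair, with a 95% CI half-width. Grids are
    aligned by intersection; ``time_range_ms`` optionally restricts the
    correlated segment.
    """
    if mode not in ("within", "between"):
        raise ValueError(f"mode must be 'within' or 'between', got {mode!r}")
    rows = []
    if mode == "within":
        for label, runs in traces.items():
            if len(runs) < 2:
                raise ValueError(f"participant {label!r} needs >= 2 runs")
            grid = _common_grid(runs)
            if time_range_ms is not None:
                grid = grid[(grid >= time_range_ms[0]) & (grid <= time_range_ms[1])]
            vecs = [_on_grid(ev, grid) for ev in runs]
            rs = [pearson_r(a, b).r
                  for a, b in itertools.combinations(vecs, 2)]
            rs = np.asarray(rs)
            se = float(rs.std(ddof=1) / math.sqrt(rs.size)) if rs.size > 1 else 0.0
            rows.append({
                "pair": label, "r": float(rs.mean()), "uncertainty": se,
                "uncertainty_kind": "standard_error", "n": rs.size,
            })
    else:
        labels = list(traces)
        if len(labels) < 2:
            raise ValueError("between mode needs >= 2 participants")
        all_runs = [ev for runs in traces.values() for ev in runs]
        grid = _common_grid(all_runs)
        if time_range_ms is not None:
            grid = grid[(grid >= time_range_ms[0]) & (grid <= time_range_ms[1])]
        means = {
            label: np.mean([_on_grid(ev, grid) for ev in runs], axis=0)
            for label, runs in traces.items()
        }
        for a, b in itertools.combinations(labels, 2):
            res = pearson_r(means[a], means[b],
                            uncertainty="ci95_halfwidth", pair=f"{a}-{b}")
            rows.append({
                "pair": res.pair, "r": res.r, "uncertainty": res.uncertainty,
                "uncertainty_kind": res.uncertainty_kind, "n": res.n,
            })
    return pd.DataFrame(rows, columns=["pair", "r", "uncertainty",
                                       "uncertainty_kind", "n"])
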