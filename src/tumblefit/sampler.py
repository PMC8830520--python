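"""Online hot/cold sampling policy.

At each training time tau the learner draws its dataset from the trailing
window [tau - W, tau] of the processed stream.  The window is split into
four regions — the hot region [tau - w, tau] of the freshest data and
three progressively older cold regions — and a fixed number of short
series starts uniformly at random inside each region (stratified
sampling).  Each short series is the next ``Ns`` consecutive processed
samples, so it carries contiguous short-term dynamics; series may cross a
region boundary but never extend past tau.

The region counts {12, 10, 9, 9} over the regions [tau-1, tau],
[tau-2, tau-1], [tau-5, tau-2], [tau-8, tau-5] define the operative
staircase history-mixing distribution (density proportional to
count/region-length, normalised over the window).  The literature also
prints the raw staircase masses {3/8, 1/4, 9/40}; they are stored here as
documentation only, since they are not normalised and are superseded by
the self-consistent counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ConfigurationError

__all__ = [
    "SamplingPolicy",
    "TrainingBatch",
    "WarmupError",
    "staircase_density",
    "draw_training_batch",
    "training_times",
]

#: Printed (unnormalised) staircase masses, kept for reference.
RAW_STAIRCASE_MASSES = (3.0 / 8.0, 1.0 / 4.0, 9.0 / 40.0)


class WarmupError(RuntimeError):
    """Raised when the stream does not yet cover a full sampling window."""


@dataclass(frozen=True)
class SamplingPolicy:
    """Stratified staircase sampling policy.

    ``region_bounds`` are offsets back from tau, strictly increasing and
    ending at the window size W; region i spans
    [tau - bounds[i], tau - bounds[i-1]) with bounds[-1] implicitly 0.
    """

    window: float = 8.0  # W, half the rotation period
    hot_width: float = 1.0  # w = W/8
    region_bounds: tuple = (1.0, 2.0, 5.0, 8.0)
    region_counts: tuple = (12, 10, 9, 9)  # most-recent first
    n_series: int = 40
    series_length: int = 10  # Ns consecutive processed samples

    def __post_init__(self):
        if sum(self.region_counts) != self.n_series:
            raise ConfigurationError(
                f"region counts {self.region_counts} must sum to "
                f"n_series={self.n_series}"
            )
        if len(self.region_bounds) != len(self.region_counts):
            raise ConfigurationError("one bound per region required")
        bounds = np.asarray(self.region_bounds, dtype=float)
        if not np.all(np.diff(bounds) > 0) or bounds[0] <= 0:
            raise ConfigurationError("region bounds must be strictly increasing")
        if bounds[-1] != self.window:
            raise ConfigurationError(
                f"region bounds must cover the window: last bound "
                f"{bounds[-1]} != W={self.window}"
            )
        if self.series_length < 1:
            raise ConfigurationError("series_length must be >= 1")
        if not 0 < self.hot_width <= self.window:
            raise ConfigurationError("need 0 < hot_width <= window")

    def region_edges(self, tau: float) -> np.ndarray:
        """Region edges [tau, tau-b1, tau-b2, ...] most-recent first."""
        return tau - np.concatenate([[0.0], np.asarray(self.region_bounds)])

    def region_lengths(self) -> np.ndarray:
        bounds = np.concatenate([[0.0], np.asarray(self.region_bounds)])
        return np.diff(bounds)


@dataclass(frozen=True)
class TrainingBatch:
    """One training dataset: ``n_series`` short contiguous series drawn at
    time tau, each with its originating region label."""

    series_list: list  # of DataFrames with processed-stream columns
    region_labels: np.ndarray  # region index per series, 0 = hot
    draw_time: float


def staircase_density(t, tau: float, policy: SamplingPolicy):
    """Normalised staircase probability density of series start times.

    Piecewise constant: proportional to region_count/region_length inside
    each region, zero outside [tau - W, tau]; integrates to 1 over the
    window.
    """
    t = np.asarray(t, dtype=float)
    lengths = policy.region_lengths()
    heights = np.asarray(policy.region_counts) / (policy.n_series * lengths)
    bounds = np.concatenate([[0.0], np.asarray(policy.region_bounds)])
    age = tau - t
    out = np.zeros_like(t, dtype=float)
    for i in range(len(lengths)):
        mask = (age >= bounds[i]) & (age <= bounds[i + 1] if i == len(lengths) - 1
                                     else age < bounds[i + 1])
        out = np.where(mask & (age >= 0), heights[i], out)
    return out if out.shape else float(out)


def draw_training_batch(
    history: pd.DataFrame,
    tau: float,
    policy: SamplingPolicy,
    rng: np.random.Generator | int | None = None,
) -> TrainingBatch:
    """Draw the stratified training batch at time tau.

    ``history`` is a processed stream (column ``gamma_t`` plus features)
    covering at least [tau - W, tau].  Exactly ``region_counts[i]`` series
    start uniformly at random within region i; each series is the next
    ``Ns`` consecutive samples and never references data after tau.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    times = history["gamma_t"].to_numpy(dtype=float)
    if len(times) == 0 or times[0] > tau - policy.window or times[-1] < tau:
        raise WarmupError(
            f"history must cover [{tau - policy.window}, {tau}]; wait until "
            f"the stream reaches tau >= W = {policy.window}"
        )
    ns = policy.series_length
    # last index usable as a series start so the series ends at or before tau
    last_valid = int(np.searchsorted(times, tau, side="right")) - ns
    if last_valid < 0:
        raise WarmupError("not enough processed samples for one short series")
    edges = policy.region_edges(tau)
    series_list, labels = [], []
    for i, count in enumerate(policy.region_counts):
        hi, lo = edges[i], edges[i + 1]  # region spans [lo, hi)
        i_lo = int(np.searchsorted(times, lo, side="left"))
        i_hi = int(np.searchsorted(times, hi, side="left")) - 1
        i_hi = min(i_hi, last_valid)
        if i_hi < i_lo:
            raise WarmupError(
                f"region [{lo}, {hi}) holds no valid series start; "
                "stream too sparse for the policy"
            )
        starts = rng.integers(i_lo, i_hi + 1, size=count)
        for s in starts:
            series_list.append(history.iloc[s : s + ns])
            labels.append(i)
    return TrainingBatch(
        series_list=series_list,
        region_labels=np.asarray(labels),
        draw_time=tau,
    )


def training_times(duration: float, policy: SamplingPolicy, stride: float):
    """Arithmetic sequence of training times tau_0 = W, tau_{k+1} =
    tau_k + stride, up to the stream duration (inclusive)."""
    if stride <= 0:
        raise ConfigurationError(f"stride must be positive, got {stride}")
    if duration < policy.window:
        return np.array([])
    n = int(np.floor((duration - policy.window) / stride + 1e-9)) + 1
    return policy.window + stride * np.arange(n)
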