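"""Windowed firing-rate estimation and the extremal-variation statistic.

Firing frequency is estimated in sliding windows (default 60 s length,
15 s step), expressed as percent change from the pre-injection baseline
mean, and summarised by the signed extremal variation Δf: the larger in
magnitude of the maximal and minimal percent change within the
post-injection response period (default 180 s).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import SpikeTrain, ValidationError

logger = logging.getLogger("vtaephys")

__all__ = [
    "RateTrace",
    "ResponseProfile",
    "compute_rate_trace",
    "baseline_mean_rate",
    "normalize_to_baseline",
    "extremal_variation",
    "aggregate_time_courses",
]

#: defaults from the recording analysis: 60 s windows advanced in 15 s steps,
#: 3 min response period, 300 s baseline.
DEFAULT_WINDOW_LENGTH = 60.0
DEFAULT_STEP = 15.0
DEFAULT_RESPONSE_PERIOD = 180.0
DEFAULT_BASELINE_DURATION = 300.0

_EPS = 1e-9  # tolerance for float window-edge comparisons


@dataclass(frozen=True)
class RateTrace:
    """Windowed firing-rate series (Hz) on an evenly spaced center grid."""

    window_centers: np.ndarray
    rates: np.ndarray
    window_length: float
    step: float

    def __post_init__(self):
        centers = np.asarray(self.window_centers, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "window_centers", centers)
        object.__setattr__(self, "rates", rates)
        if centers.size != rates.size:
            raise ValidationError("centers and rates must have equal length")
        if centers.size > 1:
            steps = np.diff(centers)
            if not np.allclose(steps, self.step, atol=1e-6):
                raise ValidationError("window centers must advance by `step`")
        if np.any(rates < 0):
            raise ValidationError("rates must be non-negative")


@dataclass(frozen=True)
class ResponseProfile:
    """Baseline-normalized rate trace with its response-period extrema.

    ``normalized_pct`` maps each window to 100·(rate − μ)/μ with μ the
    baseline mean rate, so rate = μ·(1 + v/100) recovers the raw rate.
    ``delta_f_pct`` is whichever of max/min variation has the larger
    magnitude (ties resolve to the maximum, with ``tie_flag`` set).
    """

    baseline_mean_hz: float
    window_centers: np.ndarray
    normalized_pct: np.ndarray
    window_length: float
    step: float
    response_window: Optional[tuple] = None
    max_variation_pct: Optional[float] = None
    min_variation_pct: Optional[float] = None
    delta_f_pct: Optional[float] = None
    tie_flag: bool = False

    def denormalized_rates(self) -> np.ndarray:
        return self.baseline_mean_hz * (1.0 + np.asarray(self.normalized_pct) / 100.0)


def compute_rate_trace(
    spikes,
    interval: tuple,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    step: float = DEFAULT_STEP,
) -> RateTrace:
    """Windowed firing rate over ``interval``.

    Windows are half-open ``[center − W/2, center + W/2)`` with centers at
    ``interval[0] + W/2 + k·step``; only windows fully contained in the
    interval are produced.  ``spikes`` may be a :class:`SpikeTrain` or an
    array of spike times.
    """
    if isinstance(spikes, SpikeTrain):
        times = spikes.spike_times
    else:
        times = np.asarray(spikes, dtype=float)
    lo, hi = float(interval[0]), float(interval[1])
    if window_length < step or step <= 0:
        raise ValidationError("require window_length >= step > 0")
    if hi - lo < window_length - _EPS:
        raise ValidationError("interval shorter than one window")

    n_windows = int(np.floor((hi - lo - window_length) / step + _EPS)) + 1
    centers = lo + window_length / 2.0 + step * np.arange(n_windows)
    starts = centers - window_length / 2.0
    counts = np.searchsorted(times, starts + window_length, side="left") - np.searchsorted(
        times, starts, side="left"
    )
    return RateTrace(centers, counts / window_length, window_length, step)


def baseline_mean_rate(spikes, baseline_interval: tuple) -> float:
    """Mean firing rate over the baseline interval: spike count / duration.

    This estimator is exactly conserved by ISI shuffling of the baseline
    (count and span are invariant), which keeps the surrogate normalization
    identical to the observed one.
    """
    if isinstance(spikes, SpikeTrain):
        times = spikes.spike_times
    else:
        times = np.asarray(spikes, dtype=float)
    lo, hi = float(baseline_interval[0]), float(baseline_interval[1])
    if hi <= lo:
        raise ValidationError("baseline interval must have positive length")
    count = np.searchsorted(times, hi, side="left") - np.searchsorted(
        times, lo, side="left"
    )
    return float(count) / (hi - lo)


def normalize_to_baseline(
    rate_trace: RateTrace, baseline_mean_hz: float
) -> ResponseProfile:
    """Express a rate trace as percent change from the baseline mean."""
    if baseline_mean_hz <= 0:
        raise ValidationError("silent baseline: baseline mean rate must be > 0")
    pct = 100.0 * (rate_trace.rates - baseline_mean_hz) / baseline_mean_hz
    return ResponseProfile(
        baseline_mean_hz=float(baseline_mean_hz),
        window_centers=rate_trace.window_centers,
        normalized_pct=pct,
        window_length=rate_trace.window_length,
        step=rate_trace.step,
    )


def extremal_variation(
    profile: ResponseProfile, response_window: tuple
) -> ResponseProfile:
    """Signed extremal variation Δf within the response period.

    A window belongs to the response period iff its *center* lies in
    ``(t0, t1]``.  Returns a new profile with ``max_variation_pct``,
    ``min_variation_pct`` and ``delta_f_pct`` filled; Δf is the value of
    larger magnitude, resolving exact-magnitude ties to the maximum
    (activation) with ``tie_flag`` set.
    """
    t0, t1 = float(response_window[0]), float(response_window[1])
    centers = profile.window_centers
    mask = (centers > t0 + _EPS) & (centers <= t1 + _EPS)
    if not mask.any():
        raise ValidationError("no rate windows fall inside the response window")
    vals = np.asarray(profile.normalized_pct)[mask]
    vmax, vmin = float(np.max(vals)), float(np.min(vals))
    tie = bool(np.isclose(abs(vmax), abs(vmin)) and vmax != vmin)
    delta = vmax if abs(vmax) >= abs(vmin) else vmin
    return ResponseProfile(
        baseline_mean_hz=profile.baseline_mean_hz,
        window_centers=profile.window_centers,
        normalized_pct=profile.normalized_pct,
        window_length=profile.window_length,
        step=profile.step,
        response_window=(t0, t1),
        max_variation_pct=vmax,
        min_variation_pct=vmin,
        delta_f_pct=delta,
        tie_flag=tie,
    )


def n_response_windows(
    profile_or_trace, response_window: tuple
) -> int:
    """Number of rate windows whose centers fall in ``(t0, t1]``."""
    centers = (
        profile_or_trace.window_centers
        if hasattr(profile_or_trace, "window_centers")
        else np.asarray(profile_or_trace, dtype=float)
    )
    t0, t1 = float(response_window[0]), float(response_window[1])
    return int(np.sum((centers > t0 + _EPS) & (centers <= t1 + _EPS)))


def aggregate_time_courses(
    profiles: Sequence[ResponseProfile],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean ± SEM of normalized traces across neurons.

    Profiles must share window length, step and center grid (aligned on the
    injection).  Returns ``(centers, mean_pct, sem_pct)``.  With a single
    profile the SEM is defined as 0 (with a warning) so aggregation is total.
    """
    if not profiles:
        raise ValidationError("no profiles to aggregate")
    first = profiles[0]
    for p in profiles[1:]:
        if p.window_length != first.window_length or p.step != first.step:
            raise ValidationError("profiles mix window length or step")
        if p.window_centers.size != first.window_centers.size or not np.allclose(
            p.window_centers, first.window_centers
        ):
            raise ValidationError("profiles are not aligned on a common grid")
    stack = np.vstack([np.asarray(p.normalized_pct) for p in profiles])
    mean = stack.mean(axis=0)
    if stack.shape[0] == 1:
        warnings.warn("SEM of a single profile is defined as 0", stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    return first.window_centers.copy(), mean, sem
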