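"""Postsynaptic-current analysis: template construction and matched detection.

Detection follows the classical scaled-template criterion: at every offset
the template is fit to the trace by least squares in scale and offset, and
the detection statistic is the fitted scale divided by its standard error.
Local maxima of the statistic above a criterion threshold (default 4)
become candidate events, which are kept only if the fitted amplitude
magnitude reaches at least three times the noise standard deviation.
Templates are aligned averages of at least 15 example currents,
baseline-subtracted and peak-normalized.  Noise SD is a scaled median
absolute deviation of the first-difference (high-pass) residual outside
detected events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .data_model import CurrentTrace, ValidationError

logger = logging.getLogger("vtaephys")

__all__ = [
    "EventTemplate",
    "DetectedEvent",
    "build_template",
    "estimate_noise_sd",
    "detect_events",
    "evoked_amplitude",
]

MIN_TEMPLATE_EVENTS = 15
AMPLITUDE_SD_FACTOR = 3.0
DEFAULT_CRITERION_THRESHOLD = 4.0
DEFAULT_TEMPLATE_LENGTH_MS = 30.0

_MAD_SCALE = 1.4826  # MAD → SD for Gaussian noise


@dataclass(frozen=True)
class EventTemplate:
    """Unit-peak event kernel averaged from example currents.

    The waveform includes ``pre_ms`` of pre-onset baseline so the baseline
    estimate never overlaps the event rise; detection reports onsets at the
    end of that span.
    """

    waveform: np.ndarray
    length_ms: float
    n_source_events: int
    sampling_rate: float
    pre_ms: float = 0.0

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w)
        if self.n_source_events < MIN_TEMPLATE_EVENTS:
            raise ValidationError(
                f"template requires at least {MIN_TEMPLATE_EVENTS} example currents"
            )
        # normalization uses a noise-robust (smoothed) peak estimate, so the
        # raw sample extremum may exceed 1 by residual noise
        peak = np.max(np.abs(w))
        if not 0.9 <= peak <= 2.0:
            raise ValidationError("template waveform must be peak-normalized")


@dataclass(frozen=True)
class DetectedEvent:
    """One detected synaptic current."""

    onset_time: float
    amplitude_pA: float
    detection_score: float


def build_template(
    trace: CurrentTrace,
    example_event_times: Sequence[float],
    length_ms: float = DEFAULT_TEMPLATE_LENGTH_MS,
    pre_ms: float = 5.0,
) -> EventTemplate:
    """Average ≥15 example snippets into a unit-peak template.

    Snippets span ``[onset − pre_ms, onset − pre_ms + length_ms)``, so the
    leading ``pre_ms`` of each is true baseline.  The average is
    baseline-subtracted (mean of the pre-onset span) and divided by its
    signed extremal post-onset value, so the peak sample becomes +1 and
    fitted scales recover signed amplitudes in pA.
    """
    onsets = np.sort(np.asarray(example_event_times, dtype=float))
    fs = trace.sampling_rate
    length = int(round(length_ms / 1000.0 * fs))
    pre = int(round(pre_ms / 1000.0 * fs))
    if length < 4 or length <= pre + 2:
        raise ValidationError("template length too short for the sampling rate")
    idx = np.round((onsets - trace.start_time) * fs).astype(int) - pre
    valid = (idx >= 0) & (idx + length <= trace.samples.size)
    idx = idx[valid]
    if idx.size < MIN_TEMPLATE_EVENTS:
        raise ValidationError(
            f"need at least {MIN_TEMPLATE_EVENTS} example currents, got {idx.size}"
        )
    if np.any(np.diff(idx) < length):
        raise ValidationError("example events overlap within one template length")
    snippets = np.stack([trace.samples[i : i + length] for i in idx])
    avg = snippets.mean(axis=0)
    avg = avg - avg[: max(1, pre)].mean()
    # peak estimated on a ~1 ms-smoothed copy: the raw argmax of a noisy
    # average is biased outward, which would shrink the normalized template
    width = max(3, int(round(fs / 1000.0)) | 1)
    smooth = np.convolve(avg, np.ones(width) / width, mode="same")
    post = smooth[pre:]
    peak = post[np.argmax(np.abs(post))]
    if peak == 0:
        raise ValidationError("flat template: examples contain no event")
    return EventTemplate(
        waveform=avg / peak,
        length_ms=length_ms,
        n_source_events=int(idx.size),
        sampling_rate=fs,
        pre_ms=pre_ms,
    )


def estimate_noise_sd(
    trace: CurrentTrace, exclusion_mask: Optional[np.ndarray] = None
) -> float:
    """Robust noise SD (pA) from the high-pass residual outside events.

    The residual is the first difference scaled by 1/√2 (white-noise SD
    preserving); the estimator is 1.4826 × MAD over unmasked samples.
    ``exclusion_mask`` is True at samples to exclude (detected events).
    """
    x = trace.samples
    resid = np.diff(x) / np.sqrt(2.0)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask, dtype=bool)
        if mask.size != x.size:
            raise ValidationError("exclusion mask length must match the trace")
        keep = ~(mask[1:] | mask[:-1])
        resid = resid[keep]
    if resid.size < 0.1 * trace.sampling_rate:
        raise ValidationError("need at least 100 ms of unmasked samples")
    return float(_MAD_SCALE * np.median(np.abs(resid - np.median(resid))))


def _sliding_fit(x: np.ndarray, w: np.ndarray):
    """Least-squares scale/offset fit of template ``w`` at every offset.

    Returns ``(scale, score)`` where score = scale / SE(scale).
    """
    L = w.size
    n_off = x.size - L + 1
    Sw = w.sum()
    Sww = float(np.dot(w, w))
    denom = Sww - Sw * Sw / L  # ∝ template variance; >0 for any non-flat kernel
    if denom <= 0:
        raise ValidationError("flat template cannot be fit")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    Sy = cs[L:] - cs[:-L]
    Syy = cs2[L:] - cs2[:-L]
    Swy = signal.fftconvolve(x, w[::-1], mode="valid")
    a = (Swy - Sw * Sy / L) / denom
    b = (Sy - a * Sw) / L
    sse = Syy - 2 * a * Swy - 2 * b * Sy + a * a * Sww + 2 * a * b * Sw + L * b * b
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / max(L - 2, 1) / denom)
        score = np.where(se > 0, a / se, np.sign(a) * np.inf)
    return a[:n_off], score[:n_off]


def detect_events(
    trace: CurrentTrace,
    template: EventTemplate,
    noise_sd: float,
    criterion_threshold: float = DEFAULT_CRITERION_THRESHOLD,
) -> list[DetectedEvent]:
    """Template-matched event detection with the 3×noise-SD amplitude rule.

    Candidates are local maxima of |scale/SE| above ``criterion_threshold``;
    each must have fitted |amplitude| ≥ 3×``noise_sd``.  Overlapping
    candidates within one template length are resolved greedily in favour
    of the higher score.
    """
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    w = template.waveform
    if w.size >= trace.samples.size:
        raise ValidationError("template must be shorter than the trace")
    amp, score = _sliding_fit(trace.samples, w)
    mag = np.abs(score)
    peaks, _ = signal.find_peaks(mag, height=criterion_threshold)
    peaks = peaks[np.abs(amp[peaks]) >= AMPLITUDE_SD_FACTOR * noise_sd]
    # greedy overlap resolution, refractory span of one template length
    order = peaks[np.argsort(mag[peaks])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= w.size for j in kept):
            kept.append(int(i))
    kept.sort()
    fs = trace.sampling_rate
    pre = template.pre_ms / 1000.0  # fit offset is template start; onset follows it
    return [
        DetectedEvent(
            onset_time=trace.start_time + i / fs + pre,
            amplitude_pA=float(amp[i]),
            detection_score=float(score[i]),
        )
        for i in kept
    ]


def events_to_mask(
    trace: CurrentTrace, events: Sequence[DetectedEvent], template: EventTemplate
) -> np.ndarray:
    """Boolean mask covering one template span around each detected event."""
    mask = np.zeros(trace.samples.size, dtype=bool)
    fs = trace.sampling_rate
    length = template.waveform.size
    pre = int(round(template.pre_ms / 1000.0 * fs))
    for ev in events:
        i = int(round((ev.onset_time - trace.start_time) * fs)) - pre
        mask[max(i, 0) : max(i, 0) + length] = True
    return mask


def evoked_amplitude(
    trace: CurrentTrace,
    stim_time: float,
    pre_window: tuple,
    post_window: tuple,
) -> float:
    """Evoked response amplitude: post-stimulus peak minus baseline mean.

    ``pre_window``/``post_window`` are absolute ``(start, end)`` intervals;
    the pre window must end by the stimulus and the post window must start
    at or after it.  The returned value preserves the deflection's sign.
    """
    p0, p1 = map(float, pre_window)
    q0, q1 = map(float, post_window)
    t_lo = trace.start_time
    t_hi = trace.start_time + trace.duration
    if not (t_lo <= p0 < p1 <= t_hi and t_lo <= q0 < q1 <= t_hi):
        raise ValidationError("analysis windows must lie inside the trace")
    if p1 > q0:
        raise ValidationError("pre and post windows overlap")
    if q0 < stim_time - 1e-9:
        raise ValidationError("post window must start at or after the stimulus")
    fs = trace.sampling_rate
    i = lambda t: int(round((t - trace.start_time) * fs))
    pre = trace.samples[i(p0) : i(p1)]
    post = trace.samples[i(q0) : i(q1)]
    if pre.size == 0 or post.size == 0:
        raise ValidationError("empty analysis window")
    baseline = pre.mean()
    dev = post - baseline
    return float(dev[np.argmax(np.abs(dev))])
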