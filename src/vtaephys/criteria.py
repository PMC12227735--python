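"""Putative-DA screening and the opto-tag assessment.

In vivo dopamine neurons are screened by four waveform/rate criteria
applied as strict inequalities: (i) triphasic action potential with a
marked negative deflection, (ii) total duration > 2.0 ms, (iii) start to
negative trough > 1.1 ms, (iv) slow firing, between 1 and 10 Hz.

Opto-tagging asks whether spiking probability increases within 10 ms of
light onset.  Significance is assessed with a circular-shift permutation
test (pulse onsets jointly rotated by uniform random offsets within the
epoch), which preserves the spike train's autostructure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._rng import as_rng
from .data_model import LightPulseTrain, SpikeTrain, ValidationError, WaveformFeatures

logger = logging.getLogger("vtaephys")

__all__ = ["OptoTagResult", "is_putative_da", "opto_tag_test"]

DEFAULT_TAG_WINDOW = 0.010  # s


@dataclass(frozen=True)
class OptoTagResult:
    """Outcome of the light-evoked firing-probability test."""

    p_spike_baseline: float
    p_spike_post_onset: float
    p_value: float
    tagged: bool
    n_pulses: int


_CRITERIA = (
    ("(i) triphasic action potential", lambda f: f.is_triphasic),
    ("(ii) total duration > 2.0 ms", lambda f: f.total_duration_ms > 2.0),
    ("(iii) start-to-trough > 1.1 ms", lambda f: f.start_to_trough_ms > 1.1),
    ("(iv) firing rate in (1, 10) Hz", lambda f: 1.0 < f.mean_rate_hz < 10.0),
)


def is_putative_da(features: WaveformFeatures) -> tuple[bool, list[str]]:
    """Screen a unit's waveform features against the four DA criteria.

    Returns ``(accepted, failed_reasons)``; the reasons list names every
    criterion that failed.  Thresholds are strict inequalities, so a rate
    of exactly 10 Hz is rejected.
    """
    if features is None:
        raise ValidationError("missing waveform features")
    for name in ("total_duration_ms", "start_to_trough_ms", "mean_rate_hz", "is_triphasic"):
        if getattr(features, name, None) is None:
            raise ValidationError(f"missing waveform feature: {name}")
    failed = [label for label, check in _CRITERIA if not check(features)]
    return (not failed), failed


def _fraction_with_spike(spike_times, onsets, window) -> float:
    lo = np.searchsorted(spike_times, onsets, side="right")
    hi = np.searchsorted(spike_times, onsets + window, side="right")
    return float(np.mean(hi > lo))


def opto_tag_test(
    spike_train: SpikeTrain,
    pulses: LightPulseTrain | np.ndarray,
    tag_window: float = DEFAULT_TAG_WINDOW,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    rng=None,
) -> OptoTagResult:
    """Test for a short-latency increase in firing probability after light.

    The statistic is the fraction of pulses with at least one spike in
    ``(onset, onset + tag_window]``.  The null is built by circularly
    shifting all pulse onsets by a common uniform offset within the pulse
    epoch, ``n_permutations`` times; p uses the add-one permutation rule.
    A unit is tagged iff p < ``alpha`` and the observed fraction exceeds
    the null mean.
    """
    onsets = (
        pulses.pulse_onsets
        if isinstance(pulses, LightPulseTrain)
        else np.asarray(pulses, dtype=float)
    )
    if onsets.size == 0:
        raise ValidationError("no light pulses supplied")
    if onsets.size < 10:
        raise ValidationError("opto-tag test requires at least 10 pulses")
    if onsets.size > 1 and tag_window > np.min(np.diff(onsets)):
        raise ValidationError("tag window longer than the inter-pulse interval")
    times = spike_train.spike_times
    epoch0, epoch1 = spike_train.epoch_start, spike_train.epoch_end
    span = epoch1 - epoch0
    observed = _fraction_with_spike(times, onsets, tag_window)

    rng = as_rng(rng)
    null = np.empty(n_permutations)
    rel = onsets - epoch0
    for i in range(n_permutations):
        shifted = epoch0 + (rel + rng.uniform(0.0, span)) % span
        null[i] = _fraction_with_spike(times, np.sort(shifted), tag_window)
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_permutations + 1.0)
    p_baseline = float(null.mean())
    return OptoTagResult(
        p_spike_baseline=p_baseline,
        p_spike_post_onset=observed,
        p_value=float(p),
        tagged=bool(p < alpha and observed > p_baseline),
        n_pulses=int(onsets.size),
    )
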