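"""ISI-shuffle bootstrap classification of drug-evoked responses.

The null hypothesis is that the post-injection extremal rate variation Δf
is indistinguishable from spontaneous baseline variability.  The null is
built non-parametrically: baseline interspike intervals are randomly
permuted (default 1000 times), the windowed firing rate of each surrogate
train is normalized to the original baseline mean, and the signed extremal
variation is taken over the same number of windows as contribute to the
observed response-period extremum.  A neuron is responsive when the
mid-rank percentile of its observed Δf in this null reaches ≥0.95 or
≤0.05; polarity (activated/inhibited) follows the sign of Δf.

Auxiliary procedures: the drug-vs-saline paired contrast with a
normality-screened choice between the paired t test and the Wilcoxon
signed-rank test (Holm step-down across contrasts), and the dose-response
rule labelling a neuron by its polarity at the lowest dose that evokes a
significant response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._rng import as_rng
from .data_model import SpikeTrain, ValidationError
from .rates import (
    DEFAULT_BASELINE_DURATION,
    DEFAULT_RESPONSE_PERIOD,
    DEFAULT_STEP,
    DEFAULT_WINDOW_LENGTH,
    ResponseProfile,
    baseline_mean_rate,
    compute_rate_trace,
    extremal_variation,
    normalize_to_baseline,
)

logger = logging.getLogger("vtaephys")

__all__ = [
    "NullDistribution",
    "Classification",
    "ContrastResult",
    "shuffle_isis",
    "build_null_distribution",
    "percentile_of",
    "classify_response",
    "classify_drug_response",
    "contrast_drug_vs_saline",
    "holm_correction",
    "first_significant_dose",
]

DEFAULT_N_SHUFFLES = 1000
DEFAULT_PERCENTILE_BOUNDS = (0.05, 0.95)


@dataclass(frozen=True)
class NullDistribution:
    """Bootstrap null of signed extremal variations (%) for one neuron."""

    values: np.ndarray
    n_shuffles: int
    source_neuron_id: Optional[str] = None
    seed: Optional[int] = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.size != self.n_shuffles:
            raise ValidationError("null length must equal n_shuffles")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("null values must be finite")


@dataclass(frozen=True)
class Classification:
    """Responsiveness label with its bootstrap provenance."""

    label: str  # "activated" | "inhibited" | "nonresponsive"
    percentile: float
    delta_f_pct: float
    conflict_flag: bool = False
    drug: Optional[str] = None
    dose: Optional[float] = None
    neuron_id: Optional[str] = None

    @property
    def responsive(self) -> bool:
        return self.label in ("activated", "inhibited")

    @property
    def polarity(self) -> int:
        """+1 activated, −1 inhibited, 0 nonresponsive."""
        return {"activated": 1, "inhibited": -1}.get(self.label, 0)


def shuffle_isis(baseline_spikes, rng) -> np.ndarray:
    """One ISI-shuffle surrogate of a baseline spike train.

    The surrogate starts at the first baseline spike time and its ISIs are a
    uniformly random permutation of the original ISI multiset, so spike
    count and total span are preserved exactly.
    """
    times = (
        baseline_spikes.spike_times
        if isinstance(baseline_spikes, SpikeTrain)
        else np.asarray(baseline_spikes, dtype=float)
    )
    if times.size < 3:
        raise ValidationError("insufficient baseline: need at least 3 spikes")
    rng = as_rng(rng)
    isis = np.diff(times)
    return times[0] + np.concatenate(([0.0], np.cumsum(rng.permutation(isis))))


def build_null_distribution(
    baseline_spikes,
    n_windows: int,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    step: float = DEFAULT_STEP,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng=None,
    baseline_mean_hz: Optional[float] = None,
    source_neuron_id: Optional[str] = None,
) -> NullDistribution:
    """Bootstrap null of Δf from ISI-shuffled baseline surrogates.

    Per shuffle, the windowed rate of the surrogate is computed on its own
    span, normalized to ``baseline_mean_hz`` (the *original* baseline mean;
    conserved by the shuffle), and the signed extremal percent variation is
    taken over the first ``n_windows`` windows — the same number of windows
    as contribute to the observed response-period extremum.  Deterministic
    for a fixed ``rng``/seed.
    """
    times = (
        baseline_spikes.spike_times
        if isinstance(baseline_spikes, SpikeTrain)
        else np.asarray(baseline_spikes, dtype=float)
    )
    if times.size < 3:
        raise ValidationError("insufficient baseline: need at least 3 spikes")
    if n_windows < 1:
        raise ValidationError("need at least one response window")
    isis = np.diff(times)
    span = float(isis.sum())
    needed = (n_windows - 1) * step + window_length
    if span < needed - 1e-9:
        raise ValidationError(
            f"baseline span {span:.1f}s too short for {n_windows} windows "
            f"({needed:.1f}s required)"
        )
    if baseline_mean_hz is None:
        baseline_mean_hz = times.size / span
    if baseline_mean_hz <= 0:
        raise ValidationError("baseline mean rate must be > 0")
    rng = as_rng(rng)

    # Shuffle all surrogates at once; count spikes per window per surrogate.
    perms = rng.permuted(np.tile(isis, (n_shuffles, 1)), axis=1)
    cum = np.cumsum(perms, axis=1)  # spike offsets after the first spike
    starts = step * np.arange(n_windows)
    edges = np.concatenate([starts, starts + window_length])
    counts = np.empty((n_shuffles, n_windows))
    for i in range(n_shuffles):
        idx = np.searchsorted(cum[i], edges, side="left")
        c = idx[n_windows:] - idx[:n_windows]
        # the first surrogate spike sits at offset 0, inside window 0 only
        c[0] += 1
        counts[i] = c
    pct = 100.0 * (counts / window_length - baseline_mean_hz) / baseline_mean_hz
    vmax = pct.max(axis=1)
    vmin = pct.min(axis=1)
    values = np.where(np.abs(vmax) >= np.abs(vmin), vmax, vmin)
    return NullDistribution(
        values=values,
        n_shuffles=n_shuffles,
        source_neuron_id=source_neuron_id,
    )


def percentile_of(observed_delta_f: float, null: NullDistribution | np.ndarray) -> float:
    """Mid-rank percentile of the observed Δf in the null (ties count half)."""
    vals = null.values if isinstance(null, NullDistribution) else np.asarray(null)
    if vals.size == 0:
        raise ValidationError("empty null distribution")
    below = np.count_nonzero(vals < observed_delta_f)
    ties = np.count_nonzero(vals == observed_delta_f)
    return (below + 0.5 * ties) / vals.size


def classify_response(
    delta_f_pct: float,
    percentile: float,
    bounds: tuple = DEFAULT_PERCENTILE_BOUNDS,
    **meta,
) -> Classification:
    """Label a neuron from its Δf and bootstrap percentile.

    Responsive iff the percentile reaches the outer bounds (default ≥0.95 or
    ≤0.05); activated for Δf > 0, inhibited for Δf < 0.  When the extreme
    tail and the sign of Δf disagree (including Δf == 0) the neuron is left
    nonresponsive with ``conflict_flag`` set rather than silently relabeled.
    """
    if not (np.isfinite(delta_f_pct) and np.isfinite(percentile)):
        raise ValidationError("delta_f and percentile must be finite")
    lo, hi = bounds
    if not lo < hi:
        raise ValidationError("percentile bounds must be ordered")
    upper, lower = percentile >= hi, percentile <= lo
    if upper and delta_f_pct > 0:
        return Classification("activated", percentile, delta_f_pct, False, **meta)
    if lower and delta_f_pct < 0:
        return Classification("inhibited", percentile, delta_f_pct, False, **meta)
    conflict = (upper and delta_f_pct <= 0) or (lower and delta_f_pct >= 0)
    return Classification("nonresponsive", percentile, delta_f_pct, conflict, **meta)


def classify_drug_response(
    spike_train: SpikeTrain,
    t_inject: float,
    window_length: float = DEFAULT_WINDOW_LENGTH,
    step: float = DEFAULT_STEP,
    response_period: float = DEFAULT_RESPONSE_PERIOD,
    baseline_duration: float = DEFAULT_BASELINE_DURATION,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    percentile_bounds: tuple = DEFAULT_PERCENTILE_BOUNDS,
    rng=None,
    drug: Optional[str] = None,
    dose: Optional[float] = None,
) -> tuple[Classification, ResponseProfile, NullDistribution]:
    """End-to-end bootstrap classification of one injection response.

    Computes the windowed rate from the start of the baseline to the end of
    the response period (or the epoch end if earlier), normalizes to the
    baseline mean, extracts Δf over the response window, builds the
    ISI-shuffle null from the baseline spikes, and classifies.
    """
    b0 = t_inject - baseline_duration
    if b0 < spike_train.epoch_start - 1e-9:
        raise ValidationError(
            f"{spike_train.neuron_id}: baseline extends before recording epoch"
        )
    upper = min(spike_train.epoch_end, t_inject + response_period + window_length / 2)
    trace = compute_rate_trace(spike_train, (b0, upper), window_length, step)
    mu = baseline_mean_rate(spike_train, (b0, t_inject))
    if mu <= 0:
        raise ValidationError(f"{spike_train.neuron_id}: silent baseline")
    profile = normalize_to_baseline(trace, mu)
    profile = extremal_variation(profile, (t_inject, t_inject + response_period))
    centers = profile.window_centers
    k = int(
        np.sum((centers > t_inject + 1e-9) & (centers <= t_inject + response_period + 1e-9))
    )
    baseline_spikes = spike_train.between(b0, t_inject)
    null = build_null_distribution(
        baseline_spikes,
        n_windows=k,
        window_length=window_length,
        step=step,
        n_shuffles=n_shuffles,
        rng=rng,
        baseline_mean_hz=mu,
        source_neuron_id=spike_train.neuron_id,
    )
    pct = percentile_of(profile.delta_f_pct, null)
    cls = classify_response(
        profile.delta_f_pct,
        pct,
        percentile_bounds,
        drug=drug,
        dose=dose,
        neuron_id=spike_train.neuron_id,
    )
    return cls, profile, null


# ---------------------------------------------------------------------------
# Drug-vs-saline contrast and dose-response rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastResult:
    """Paired drug-vs-saline contrast on per-neuron Δf values."""

    n: int
    test: str  # "paired_t" | "wilcoxon" | "degenerate"
    statistic: float
    p_value: float
    shapiro_p: float
    mean_difference: float


def contrast_drug_vs_saline(
    drug_delta_f: Sequence[float], saline_delta_f: Sequence[float]
) -> ContrastResult:
    """Paired location test of drug vs saline extremal variations.

    Test selection follows a normality screen on the paired differences:
    Shapiro-Wilk p > 0.05 → paired t test; otherwise Wilcoxon signed-rank.
    """
    drug = np.asarray(drug_delta_f, dtype=float)
    sal = np.asarray(saline_delta_f, dtype=float)
    if drug.size != sal.size:
        raise ValidationError("paired contrast requires equal-length lists")
    if drug.size < 3:
        raise ValidationError("paired contrast requires at least 3 pairs")
    diff = drug - sal
    if np.ptp(diff) == 0:
        # identical pairs (incl. all-zero differences): nothing to test
        return ContrastResult(diff.size, "degenerate", 0.0, 1.0, 1.0, float(diff.mean()))
    shapiro_p = float(stats.shapiro(diff).pvalue)
    if shapiro_p > 0.05:
        res = stats.ttest_rel(drug, sal)
        return ContrastResult(
            diff.size, "paired_t", float(res.statistic), float(res.pvalue),
            shapiro_p, float(diff.mean()),
        )
    res = stats.wilcoxon(drug, sal)
    return ContrastResult(
        diff.size, "wilcoxon", float(res.statistic), float(res.pvalue),
        shapiro_p, float(diff.mean()),
    )


def holm_correction(p_values: Sequence[float], alpha: float = 0.05):
    """Holm sequential step-down across multiple contrasts.

    Returns ``(reject, adjusted_p)`` arrays in the input order.
    """
    from statsmodels.stats.multitest import multipletests

    reject, adjusted, _, _ = multipletests(p_values, alpha=alpha, method="holm")
    return reject, adjusted


def first_significant_dose(
    dose_classifications: Sequence[tuple[float, Classification]],
) -> str:
    """Overall polarity from a dose series, ordered by ascending dose.

    The label is the polarity at the lowest dose whose bootstrap
    classification is responsive; ``"unclassified"`` if no dose is.
    """
    if not dose_classifications:
        raise ValidationError("need at least one tested dose")
    doses = [d for d, _ in dose_classifications]
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValidationError("doses must be strictly ascending")
    for _, cls in dose_classifications:
        if cls.responsive:
            return cls.label
    return "unclassified"
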