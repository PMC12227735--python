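"""Synthetic spike trains, populations and current traces with ground truth.

The generators emulate the statistical structure the analysis assumes:

* baseline dopamine-like firing at 1–10 Hz with irregular but
  sub-Poisson ISIs (gamma renewal, shape κ=2 by default — DA firing is
  more regular than Poisson, and the ISI-shuffle null is only
  non-degenerate for irregular trains);
* injection-locked rate modulation of either polarity lasting a ~3-min
  response period (plateau kernel with 10 s linear ramps by default);
* mixed populations of activated/inhibited/non-responsive neurons with
  projection-dependent polarity composition and a tunable cross-drug
  polarity-concordance level ρ;
* noisy voltage-clamp traces containing biexponential synaptic events.

Every generator is deterministic for a fixed seed and emits ground truth
sufficient to score the downstream stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng, child_rng
from .data_model import (
    CurrentTrace,
    InjectionEvent,
    NeuronRecord,
    SpikeTrain,
    Substance,
    ValidationError,
)

logger = logging.getLogger("vtaephys")

__all__ = [
    "NeuronSimSpec",
    "PopulationSpec",
    "TwoDrugProtocol",
    "simulate_neuron",
    "simulate_population",
    "simulate_current_trace",
]

_KERNELS = ("plateau", "difference_of_exponentials")


@dataclass(frozen=True)
class NeuronSimSpec:
    """Parameters of one simulated neuron's drug response.

    ``modulation_amplitude_pct`` is the planted Δf target: the peak percent
    rate change relative to baseline (signed).  ``isi_shape`` is the gamma
    shape κ of the renewal process (κ=1 reduces to Poisson).
    """

    baseline_rate_hz: float = 5.0
    isi_shape: float = 2.0
    modulation_amplitude_pct: float = 0.0
    onset_latency_s: float = 0.0
    response_duration_s: float = 180.0
    kernel: str = "plateau"
    ramp_s: float = 10.0
    tau_rise_s: float = 10.0
    tau_decay_s: float = 60.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.baseline_rate_hz <= 0:
            raise ValidationError("baseline rate must be positive")
        if self.isi_shape < 1:
            raise ValidationError("gamma shape must be >= 1")
        if self.kernel not in _KERNELS:
            raise ValidationError(f"unknown kernel {self.kernel!r}")


def _kernel_values(spec: NeuronSimSpec, u: np.ndarray) -> np.ndarray:
    """Unit response kernel g on times-since-injection ``u`` (peak 1)."""
    g = np.zeros_like(u)
    lat, dur = spec.onset_latency_s, spec.response_duration_s
    inside = (u >= lat) & (u <= lat + dur)
    v = u[inside] - lat
    if spec.kernel == "plateau":
        ramp = min(spec.ramp_s, dur / 2.0)
        vals = np.ones_like(v)
        if ramp > 0:
            vals = np.minimum(vals, v / ramp)
            vals = np.minimum(vals, (dur - v) / ramp)
        g[inside] = np.clip(vals, 0.0, 1.0)
    else:  # difference of exponentials, peak-normalized
        tr, td = spec.tau_rise_s, spec.tau_decay_s
        t_peak = np.log(td / tr) * tr * td / (td - tr)
        peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
        g[inside] = (np.exp(-v / td) - np.exp(-v / tr)) / peak
    return g


def simulate_neuron(
    spec: NeuronSimSpec,
    epoch: tuple = (0.0, 480.0),
    injection_times: Sequence[float] = (300.0,),
    modulations_pct: Optional[Sequence[float]] = None,
    rng=None,
    neuron_id: str = "sim",
    dt: float = 0.01,
) -> SpikeTrain:
    """Time-rescaled gamma renewal spike train with injection-locked modulation.

    Intensity ``λ(t) = λ0 · max(0, 1 + Σ_j (m_j/100)·g(t − t_j))`` with g the
    unit kernel; gamma(κ, 1/κ) intervals on operational time are mapped back
    through the inverse integrated intensity.  ``modulations_pct`` gives one
    amplitude per injection (defaults to the spec amplitude for each).
    Deterministic for a fixed ``rng`` / ``spec.seed``.
    """
    rng = as_rng(rng if rng is not None else spec.seed)
    t0, t1 = float(epoch[0]), float(epoch[1])
    if t1 <= t0:
        raise ValidationError("epoch must have positive length")
    inj = np.asarray(injection_times, dtype=float)
    if modulations_pct is None:
        modulations_pct = [spec.modulation_amplitude_pct] * inj.size
    if len(modulations_pct) != inj.size:
        raise ValidationError("one modulation amplitude per injection required")

    grid = np.arange(t0, t1 + dt, dt)
    mod = np.zeros_like(grid)
    for tj, mj in zip(inj, modulations_pct):
        mod += (mj / 100.0) * _kernel_values(spec, grid - tj)
    lam = spec.baseline_rate_hz * np.maximum(0.0, 1.0 + mod)
    # integrated intensity (trapezoid) and its inverse by interpolation
    big_lambda = np.concatenate(([0.0], np.cumsum((lam[1:] + lam[:-1]) / 2.0 * dt)))
    total = big_lambda[-1]

    kappa = spec.isi_shape
    ops = np.empty(0)
    last = 0.0
    while last < total:
        n_draw = int((total - last) + 10.0 * np.sqrt(total + 1) + 50)
        ops = np.concatenate([ops, last + np.cumsum(rng.gamma(kappa, 1.0 / kappa, n_draw))])
        last = ops[-1]
    ops = ops[ops <= total]
    times = np.interp(ops, big_lambda, grid)
    times = times[(times >= t0) & (times <= t1)]
    if times.size > 1:  # flat-intensity stretches can collapse samples
        times = times[np.concatenate(([True], np.diff(times) > 0))]
    return SpikeTrain(neuron_id, times, t0, t1)


@dataclass(frozen=True)
class TwoDrugProtocol:
    """Timing of consecutive drug-1 / drug-2 injections in one session."""

    baseline_duration: float = 300.0
    response_period: float = 180.0
    washout: float = 300.0
    drug1: Substance = Substance.NICOTINE
    dose1: float = 30.0
    drug2: Substance = Substance.ETHANOL
    dose2: float = 250.0

    @property
    def t_inject1(self) -> float:
        return self.baseline_duration

    @property
    def t_inject2(self) -> float:
        return self.baseline_duration + self.response_period + self.washout

    @property
    def epoch(self) -> tuple:
        return (0.0, self.t_inject2 + self.response_period)


@dataclass(frozen=True)
class PopulationSpec:
    """Composition of a simulated two-drug population.

    Default fractions follow the observed nicotine response composition
    (≈57% activated, 39% inhibited, 4% non-responsive of 72 neurons) and
    the default concordance ρ=0.8 matches the observed cross-drug polarity
    agreement.  ``projection_polarity_map``, when given, assigns a
    projection target per neuron and draws drug-1 polarity from that
    projection's composition instead of the global fractions.
    """

    n_neurons: int = 72
    fractions: tuple = (0.57, 0.39, 0.04)  # activated, inhibited, nonresponsive
    cross_drug_concordance: float = 0.8
    modulation_amplitude_pct: float = 40.0
    baseline_rate_hz: float = 5.0
    isi_shape: float = 2.0
    projection_polarity_map: Optional[dict] = None
    projection_weights: Optional[dict] = None
    dose_thresholds: Optional[tuple] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValidationError("need at least one neuron")
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValidationError("fractions must sum to 1")
        if not 0.0 <= self.cross_drug_concordance <= 1.0:
            raise ValidationError("concordance must be a probability")
        if self.projection_polarity_map is not None:
            for proj, comp in self.projection_polarity_map.items():
                if proj not in ("NAc", "Amg", "unknown"):
                    raise ValidationError(f"unknown projection {proj!r}")
                if len(comp) != 3 or not np.isclose(sum(comp), 1.0) or min(comp) < 0:
                    raise ValidationError(
                        f"invalid polarity composition for projection {proj!r}"
                    )


def _draw_polarity(rng, composition) -> int:
    return int(rng.choice([1, -1, 0], p=np.asarray(composition, dtype=float)))


def simulate_population(
    pop_spec: PopulationSpec,
    protocol: Optional[TwoDrugProtocol] = None,
    seed: Optional[int] = None,
) -> tuple[list[NeuronRecord], pd.DataFrame]:
    """Simulate a two-drug population with ground-truth labels.

    Each neuron receives both injections in one session.  Drug-2 polarity
    equals drug-1 polarity with probability ρ (flipped otherwise);
    non-responders respond to neither drug.  Returns the records and a
    ground-truth table (polarity per drug, projection, planted amplitudes).
    """
    protocol = protocol or TwoDrugProtocol()
    root = seed if seed is not None else (pop_spec.seed or 0)
    records: list[NeuronRecord] = []
    truth_rows = []
    projections = (
        list(pop_spec.projection_polarity_map) if pop_spec.projection_polarity_map else None
    )
    if projections:
        weights = np.array(
            [
                (pop_spec.projection_weights or {}).get(p, 1.0 / len(projections))
                for p in projections
            ]
        )
        if not np.isclose(weights.sum(), 1.0):
            raise ValidationError("projection weights must sum to 1")

    for i in range(pop_spec.n_neurons):
        nid = f"sim{i:04d}"
        rng = child_rng(root, nid)
        if projections:
            proj = str(rng.choice(projections, p=weights))
            pol1 = _draw_polarity(rng, pop_spec.projection_polarity_map[proj])
        else:
            proj = "unknown"
            pol1 = _draw_polarity(rng, pop_spec.fractions)
        if pol1 == 0:
            pol2 = 0
        else:
            pol2 = pol1 if rng.random() < pop_spec.cross_drug_concordance else -pol1
        m1 = pol1 * pop_spec.modulation_amplitude_pct
        m2 = pol2 * pop_spec.modulation_amplitude_pct

        spec = NeuronSimSpec(
            baseline_rate_hz=pop_spec.baseline_rate_hz,
            isi_shape=pop_spec.isi_shape,
            response_duration_s=protocol.response_period,
        )
        train = simulate_neuron(
            spec,
            epoch=protocol.epoch,
            injection_times=(protocol.t_inject1, protocol.t_inject2),
            modulations_pct=(m1, m2),
            rng=rng,
            neuron_id=nid,
        )
        records.append(
            NeuronRecord(
                neuron_id=nid,
                spike_train=train,
                injections=[
                    InjectionEvent(protocol.t_inject1, protocol.drug1, protocol.dose1),
                    InjectionEvent(protocol.t_inject2, protocol.drug2, protocol.dose2),
                ],
                projection=proj,
            )
        )
        truth_rows.append(
            {
                "neuron_id": nid,
                "projection": proj,
                "polarity_drug1": pol1,
                "polarity_drug2": pol2,
                "amplitude_drug1_pct": m1,
                "amplitude_drug2_pct": m2,
            }
        )
    return records, pd.DataFrame(truth_rows)


def simulate_current_trace(
    duration_s: float,
    sampling_rate: float = 10_000.0,
    noise_sd: float = 5.0,
    event_rate_hz: float = 1.0,
    amplitude_mean_pA: float = -30.0,
    amplitude_cv: float = 0.3,
    tau_rise_ms: float = 1.0,
    tau_decay_ms: float = 8.0,
    stim_times: Optional[Sequence[float]] = None,
    evoked_amplitude_pA: float = -60.0,
    rng=None,
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Gaussian-noise current trace with biexponential synaptic events.

    Spontaneous events occur at Poisson times with lognormal amplitude
    magnitudes (mean |``amplitude_mean_pA``|, CV ``amplitude_cv``, sign of
    the mean); evoked events of fixed amplitude are added at
    ``stim_times``.  Returns the trace and a ground-truth event table
    (onset, amplitude, kind).
    """
    if sampling_rate < 1000:
        raise ValidationError("sampling_rate must be at least 1 kHz")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    rng = as_rng(rng)
    n = int(round(duration_s * sampling_rate))
    x = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)

    # peak-normalized biexponential kernel
    tr, td = tau_rise_ms / 1000.0, tau_decay_ms / 1000.0
    klen = int(round((tr + 6 * td) * sampling_rate))
    ku = np.arange(klen) / sampling_rate
    kern = np.exp(-ku / td) - np.exp(-ku / tr)
    kern /= kern.max()

    rows = []

    def _plant(t, amp, kind):
        i = int(round(t * sampling_rate))
        if not 0 <= i < n:
            return
        seg = min(klen, n - i)
        x[i : i + seg] += amp * kern[:seg]
        rows.append({"onset_s": i / sampling_rate, "amplitude_pA": amp, "kind": kind})

    n_events = rng.poisson(event_rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_s, n_events))
    sign = np.sign(amplitude_mean_pA) or 1.0
    sigma2 = np.log(1.0 + amplitude_cv**2)
    mu_log = np.log(abs(amplitude_mean_pA)) - sigma2 / 2.0
    amps = sign * rng.lognormal(mu_log, np.sqrt(sigma2), n_events)
    for t, a in zip(onsets, amps):
        _plant(t, a, "spontaneous")
    for t in np.asarray(stim_times if stim_times is not None else [], dtype=float):
        _plant(t, evoked_amplitude_pA, "evoked")

    truth = pd.DataFrame(rows, columns=["onset_s", "amplitude_pA", "kind"])
    truth = truth.sort_values("onset_s", ignore_index=True)
    trace = CurrentTrace(
        samples=x,
        sampling_rate=sampling_rate,
        stim_times=None if stim_times is None else np.asarray(stim_times, dtype=float),
    )
    return trace, truth
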