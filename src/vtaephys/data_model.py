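"""Domain types and plain-text I/O shared by every analysis stage.

All times are seconds on the recording clock; firing rates are Hz; currents
are pA.  File formats are deliberately minimal and text-based:

* spike tables — CSV with header ``neuron_id,spike_time_s``;
* session metadata — JSON (YAML accepted only via an explicit flag) with
  keys ``injections``, ``light_pulses``, ``projection``, ``coordinates_mm``;
* current traces — CSV with header ``time_s,current_pA``;
* reports — CSV table plus a JSON run manifest (config, seed, versions).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("vtaephys")

__all__ = [
    "ValidationError",
    "ParseError",
    "Substance",
    "DOSE_UNITS",
    "SpikeTrain",
    "InjectionEvent",
    "LightPulseTrain",
    "CurrentTrace",
    "WaveformFeatures",
    "NeuronRecord",
    "SessionMetadata",
    "read_spike_table",
    "write_spike_table",
    "read_session_metadata",
    "read_current_trace",
    "write_report",
]


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class Substance(str, enum.Enum):
    SALINE = "saline"
    NICOTINE = "nicotine"
    ETHANOL = "ethanol"
    CO_INJECTION = "co-injection"


#: Expected dose units per substance (i.v. injections).  Saline carries no
#: dose; co-injections mix units and are not unit-checked.
DOSE_UNITS = {Substance.NICOTINE: "ug/kg", Substance.ETHANOL: "mg/kg"}

_UNIT_ALIASES = {"µg/kg": "ug/kg", "μg/kg": "ug/kg", "ug/kg": "ug/kg", "mg/kg": "mg/kg"}


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one neuron in one session.

    ``spike_times`` must be strictly increasing and lie within
    ``[epoch_start, epoch_end]``.
    """

    neuron_id: str
    spike_times: np.ndarray
    epoch_start: float
    epoch_end: float

    def __post_init__(self):
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.epoch_end <= self.epoch_start:
            raise ValidationError(
                f"{self.neuron_id}: epoch_end must exceed epoch_start"
            )
        if times.size:
            if not np.all(np.diff(times) > 0):
                raise ValidationError(
                    f"{self.neuron_id}: spike times must be strictly increasing"
                )
            if times[0] < self.epoch_start or times[-1] > self.epoch_end:
                raise ValidationError(
                    f"{self.neuron_id}: spike times outside epoch "
                    f"[{self.epoch_start}, {self.epoch_end}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals, seconds."""
        return np.diff(self.spike_times)

    def between(self, t0: float, t1: float) -> np.ndarray:
        """Spike times in the half-open interval ``[t0, t1)``."""
        lo, hi = np.searchsorted(self.spike_times, [t0, t1], side="left")
        return self.spike_times[lo:hi]


@dataclass(frozen=True)
class InjectionEvent:
    """One i.v. injection: time, substance, dose with units."""

    time: float
    substance: Substance
    dose: Optional[float] = None
    dose_units: Optional[str] = None

    def __post_init__(self):
        sub = Substance(self.substance)
        object.__setattr__(self, "substance", sub)
        if sub is Substance.SALINE:
            return  # dose ignored for vehicle
        if self.dose is None or self.dose <= 0:
            raise ValidationError(f"{sub.value} injection requires dose > 0")
        if self.dose_units is not None:
            units = _UNIT_ALIASES.get(self.dose_units, self.dose_units)
            object.__setattr__(self, "dose_units", units)
            expected = DOSE_UNITS.get(sub)
            if expected is not None and units != expected:
                raise ValidationError(
                    f"{sub.value} dose units must be {expected}, got {units}"
                )


_PULSE_PATTERNS = ("regular_10Hz", "burst_20Hz", "continuous")


@dataclass(frozen=True)
class LightPulseTrain:
    """Optogenetic stimulation pulses (onsets in seconds, width in seconds)."""

    pulse_onsets: np.ndarray
    pulse_width: float
    pattern: str = "regular_10Hz"

    def __post_init__(self):
        onsets = np.asarray(self.pulse_onsets, dtype=float)
        object.__setattr__(self, "pulse_onsets", onsets)
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError("pulse onsets must be strictly increasing")
        if self.pulse_width <= 0:
            raise ValidationError("pulse width must be positive")
        if self.pattern not in _PULSE_PATTERNS:
            raise ValidationError(f"unknown pulse pattern {self.pattern!r}")


@dataclass(frozen=True)
class CurrentTrace:
    """Regularly sampled voltage-clamp current (pA)."""

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    stim_times: Optional[np.ndarray] = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("current samples must be finite")
        if self.stim_times is not None:
            object.__setattr__(
                self, "stim_times", np.asarray(self.stim_times, dtype=float)
            )

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class WaveformFeatures:
    """Extracellular action-potential features used for DA screening.

    ``is_triphasic`` is supplied by the experimenter (spike shape inspection),
    not computed here.
    """

    total_duration_ms: float
    start_to_trough_ms: float
    mean_rate_hz: float
    is_triphasic: bool

    def __post_init__(self):
        if self.total_duration_ms <= 0 or self.start_to_trough_ms <= 0:
            raise ValidationError("waveform durations must be positive")
        if self.mean_rate_hz < 0:
            raise ValidationError("mean rate must be non-negative")


@dataclass
class NeuronRecord:
    """One neuron with its session events and optional anatomy/waveform."""

    neuron_id: str
    spike_train: SpikeTrain
    injections: list = field(default_factory=list)
    projection: str = "unknown"
    coordinates_mm: Optional[tuple] = None
    waveform_features: Optional[WaveformFeatures] = None
    light_pulses: Optional[LightPulseTrain] = None

    def __post_init__(self):
        if self.projection not in ("NAc", "Amg", "unknown"):
            raise ValidationError(f"unknown projection {self.projection!r}")
        times = [inj.time for inj in self.injections]
        if times != sorted(times):
            raise ValidationError("injections must be sorted by time")


@dataclass
class SessionMetadata:
    """Typed contents of a session metadata file."""

    injections: list = field(default_factory=list)
    light_pulses: Optional[LightPulseTrain] = None
    projection: str = "unknown"
    coordinates_mm: Optional[tuple] = None
    epoch: Optional[tuple] = None
    config_overrides: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_spike_table(path, epochs: Optional[dict] = None) -> list[SpikeTrain]:
    """Read a spike table CSV (header ``neuron_id,spike_time_s``).

    Returns one :class:`SpikeTrain` per neuron id, in order of first
    appearance, spike times sorted.  ``epochs`` optionally maps neuron id to
    ``(start, end)``; otherwise the epoch is inferred as
    ``[first_spike - 1 s, last_spike + 1 s]`` (logged as inferred).
    Duplicate timestamps within a neuron raise :class:`ValidationError`;
    malformed rows raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    required = {"neuron_id", "spike_time_s"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must contain {sorted(required)}")
    if df.empty:
        return []
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = times.isna() | df["neuron_id"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: malformed row at line {line}")
    # exact round-trip parse (pandas' fast float path can drop the last ulp)
    df = df.assign(spike_time_s=df["spike_time_s"].astype(float))

    trains = []
    for nid, grp in df.groupby("neuron_id", sort=False):
        t = np.sort(grp["spike_time_s"].to_numpy())
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(f"{path}: duplicate spike times for neuron {nid!r}")
        if epochs and nid in epochs:
            start, end = epochs[nid]
        else:
            start, end = float(t[0]) - 1.0, float(t[-1]) + 1.0
            logger.info("epoch for %s inferred as [%.3f, %.3f]", nid, start, end)
        trains.append(SpikeTrain(str(nid), t, start, end))
    return trains


def write_spike_table(trains: Sequence[SpikeTrain], path) -> None:
    """Write spike trains as CSV; float repr round-trips to full precision."""
    rows = [
        {"neuron_id": tr.neuron_id, "spike_time_s": t}
        for tr in trains
        for t in tr.spike_times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"]).to_csv(
        path, index=False
    )


def _parse_metadata_dict(obj: dict) -> SessionMetadata:
    injections = []
    for i, inj in enumerate(obj.get("injections", [])):
        if "time" not in inj:
            raise ValidationError(f"injection #{i}: missing 'time'")
        try:
            substance = Substance(inj.get("substance", ""))
        except ValueError:
            raise ValidationError(
                f"injection #{i}: unknown substance {inj.get('substance')!r}"
            ) from None
        injections.append(
            InjectionEvent(
                time=float(inj["time"]),
                substance=substance,
                dose=None if inj.get("dose") is None else float(inj["dose"]),
                dose_units=inj.get("units"),
            )
        )
    pulses = None
    if "light_pulses" in obj and obj["light_pulses"]:
        lp = obj["light_pulses"]
        pulses = LightPulseTrain(
            pulse_onsets=np.asarray(lp["onsets"], dtype=float),
            pulse_width=float(lp.get("width", 0.005)),
            pattern=lp.get("pattern", "regular_10Hz"),
        )
    coords = obj.get("coordinates_mm")
    epoch = obj.get("epoch")
    return SessionMetadata(
        injections=injections,
        light_pulses=pulses,
        projection=obj.get("projection", "unknown"),
        coordinates_mm=None if coords is None else tuple(coords),
        epoch=None if epoch is None else (float(epoch[0]), float(epoch[1])),
        config_overrides=obj.get("config", {}),
    )


def read_session_metadata(path, allow_yaml: bool = False) -> SessionMetadata:
    """Read session metadata (canonical dialect: JSON).

    YAML is accepted only when ``allow_yaml=True``.  Unknown substances and
    missing injection times raise :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    if allow_yaml:
        import yaml

        obj = yaml.safe_load(text)
    else:
        obj = json.loads(text)
    if not isinstance(obj, dict):
        raise ParseError(f"{path}: metadata must be a mapping")
    return _parse_metadata_dict(obj)


def read_current_trace(path) -> CurrentTrace:
    """Read a current trace CSV (``time_s,current_pA``, uniform sampling)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "current_pA"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: header must contain {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValidationError(f"{path}: sampling must be uniform")
    return CurrentTrace(
        samples=df["current_pA"].to_numpy(dtype=float),
        sampling_rate=1.0 / float(dt[0]),
        start_time=float(t[0]),
    )


def write_report(rows, out_prefix, config=None, seed=None) -> tuple[Path, Path]:
    """Write a result table and its run manifest.

    ``rows`` is a DataFrame or list of dicts; written to ``<prefix>.csv``.
    The manifest ``<prefix>.manifest.json`` records config, seed and library
    versions.  Output is deterministic: identical inputs give byte-identical
    files (no timestamps).
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    csv_path = out_prefix.with_suffix(".csv")
    df.to_csv(csv_path, index=False)

    if config is not None and dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "vtaephys": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_rows": int(len(df)),
    }
    manifest_path = out_prefix.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return csv_path, manifest_path
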