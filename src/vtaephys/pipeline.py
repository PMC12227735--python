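"""End-to-end orchestration: one config, one seed, reproducible reports.

``run_classify`` applies the bootstrap classification to every injection of
every neuron; ``run_concordance`` pairs two classification reports and runs
the surrogate permutation test.  Per-neuron RNG streams are derived from
the root seed by stable hashing of the neuron id and drug, so results do
not depend on processing order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .bootstrap import classify_drug_response
from .concordance import (
    polarity_concordance,
    response_correlation,
    surrogate_concordance_test,
)
from .data_model import NeuronRecord, ValidationError

logger = logging.getLogger("vtaephys")

__all__ = ["RunConfig", "run_classify", "run_concordance", "confusion_counts"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis parameters shared by all stages (times in seconds)."""

    window_length: float = 60.0
    step: float = 15.0
    response_period: float = 180.0
    baseline_duration: float = 300.0
    n_shuffles: int = 1000
    percentile_bounds: tuple = (0.05, 0.95)
    n_surrogates: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in (
            "window_length", "step", "response_period",
            "baseline_duration", "n_shuffles", "n_surrogates", "alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.percentile_bounds
        if not 0 <= lo < hi <= 1:
            raise ValidationError("percentile bounds must satisfy 0 <= lo < hi <= 1")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        obj = json.loads(Path(path).read_text())
        if "percentile_bounds" in obj:
            obj["percentile_bounds"] = tuple(obj["percentile_bounds"])
        return cls(**obj)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_classify(
    records: Sequence[NeuronRecord], config: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Bootstrap-classify every injection of every neuron.

    Returns one row per (neuron, injection): label, Δf, percentile, baseline
    rate, conflict flag.  Neurons whose baseline is unusable (too short,
    silent, or outside the epoch) are skipped with a logged reason and
    reported with label ``"skipped"``.
    """
    config = config or RunConfig()
    rows = []
    for rec in records:
        for j, inj in enumerate(rec.injections):
            drug = inj.substance.value
            rng = child_rng(config.seed, rec.neuron_id, drug, j)
            try:
                cls, profile, _ = classify_drug_response(
                    rec.spike_train,
                    inj.time,
                    window_length=config.window_length,
                    step=config.step,
                    response_period=config.response_period,
                    baseline_duration=config.baseline_duration,
                    n_shuffles=config.n_shuffles,
                    percentile_bounds=config.percentile_bounds,
                    rng=rng,
                    drug=drug,
                    dose=inj.dose,
                )
            except ValidationError as exc:
                logger.warning("skipping %s/%s: %s", rec.neuron_id, drug, exc)
                rows.append(
                    {
                        "neuron_id": rec.neuron_id,
                        "drug": drug,
                        "dose": inj.dose,
                        "label": "skipped",
                        "delta_f_pct": np.nan,
                        "percentile": np.nan,
                        "baseline_hz": np.nan,
                        "conflict": False,
                        "projection": rec.projection,
                        "reason": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "neuron_id": rec.neuron_id,
                    "drug": drug,
                    "dose": inj.dose,
                    "label": cls.label,
                    "delta_f_pct": cls.delta_f_pct,
                    "percentile": cls.percentile,
                    "baseline_hz": profile.baseline_mean_hz,
                    "conflict": cls.conflict_flag,
                    "projection": rec.projection,
                    "reason": "",
                }
            )
    columns = [
        "neuron_id", "drug", "dose", "label", "delta_f_pct", "percentile",
        "baseline_hz", "conflict", "projection", "reason",
    ]
    return pd.DataFrame(rows, columns=columns)


_POLARITY = {"activated": 1, "inhibited": -1}


def run_concordance(
    report1: pd.DataFrame,
    report2: pd.DataFrame,
    config: Optional[RunConfig] = None,
) -> dict:
    """Cross-drug concordance between two classification reports.

    Reports are joined on neuron id; only neurons responsive under both
    drugs enter the concordance (exclusions are logged).  Returns the
    concordance counts, the surrogate-test p-value, and the Pearson
    correlation of Δf magnitudes where computable.
    """
    config = config or RunConfig()
    merged = report1.merge(report2, on="neuron_id", suffixes=("_1", "_2"))
    if merged.empty:
        raise ValidationError("reports share no neuron ids")
    responsive = merged[
        merged["label_1"].isin(_POLARITY) & merged["label_2"].isin(_POLARITY)
    ]
    n_excluded = len(merged) - len(responsive)
    if n_excluded:
        logger.info("excluded %d neurons not responsive to both drugs", n_excluded)
    if responsive.empty:
        raise ValidationError("no neuron is responsive to both drugs")
    pairs = [
        (_POLARITY[a], _POLARITY[b])
        for a, b in zip(responsive["label_1"], responsive["label_2"])
    ]
    conc = polarity_concordance(pairs)
    test = surrogate_concordance_test(
        pairs,
        n_surrogates=config.n_surrogates,
        rng=child_rng(config.seed, "concordance"),
    )
    result = {
        "n_pairs": conc.n_pairs,
        "n_concordant": conc.n_concordant,
        "n_discordant": conc.n_discordant,
        "percent_concordant": conc.percent_concordant,
        "surrogate_p_value": test.p_value,
        "n_surrogates": test.n_surrogates,
        "n_excluded": n_excluded,
    }
    x = responsive["delta_f_pct_1"].to_numpy()
    y = responsive["delta_f_pct_2"].to_numpy()
    if len(responsive) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        r, t, dof, p = response_correlation(x, y)
        result.update(
            {"pearson_r": r, "pearson_t": t, "pearson_dof": dof, "pearson_p": p}
        )
    return result


def confusion_counts(truth_labels, predicted_labels) -> pd.DataFrame:
    """Truth-vs-predicted label cross-tabulation for recovery checks."""
    return pd.crosstab(
        pd.Series(truth_labels, name="truth"),
        pd.Series(predicted_labels, name="predicted"),
    )
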