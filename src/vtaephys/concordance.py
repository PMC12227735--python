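"""Cross-drug polarity concordance and its pooled-surrogate permutation test.

A neuron responsive to both drugs contributes one polarity pair (sign of
Δf under each drug).  Concordance is the percentage of pairs with equal
signs.  Significance against chance pairing is assessed by a permutation
test: each surrogate re-pairs the first drug's polarities with an
independent random permutation of the second drug's polarities — pooling
the two response groups destroys the within-neuron pairing while
preserving each drug's response composition — and the p-value counts how
often a surrogate concordance reaches the observed one (add-one rule).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np

from ._rng import as_rng
from .data_model import ValidationError

logger = logging.getLogger("vtaephys")

__all__ = [
    "ConcordanceResult",
    "SurrogateTest",
    "polarity_concordance",
    "surrogate_concordance_test",
    "exhaustive_concordance_test",
    "response_correlation",
]

DEFAULT_N_SURROGATES = 10_000


def _polarity_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Coerce pairs of polarities (+1/−1, 'activated'/'inhibited', or
    Classification objects) into two sign arrays."""

    def sign_of(x):
        if hasattr(x, "polarity"):
            x = x.polarity
        if isinstance(x, str):
            x = {"activated": 1, "inhibited": -1}.get(x, 0)
        x = int(x)
        if x not in (-1, 1):
            raise ValidationError(
                "concordance requires responsive polarities (+1/-1); "
                "exclude nonresponsive neurons upstream"
            )
        return x

    a = np.array([sign_of(p) for p, _ in pairs], dtype=int)
    b = np.array([sign_of(q) for _, q in pairs], dtype=int)
    return a, b


@dataclass(frozen=True)
class ConcordanceResult:
    """Counts and percentage of same-polarity two-drug response pairs."""

    n_concordant: int
    n_discordant: int
    percent_concordant: float
    pairs: tuple

    @property
    def n_pairs(self) -> int:
        return self.n_concordant + self.n_discordant


@dataclass(frozen=True)
class SurrogateTest:
    """Permutation test of observed concordance against chance pairing."""

    observed_percent: float
    surrogate_percents: np.ndarray
    p_value: float
    n_surrogates: int
    seed: Optional[int] = None


def polarity_concordance(pairs: Sequence) -> ConcordanceResult:
    """Concordance of two-drug polarity pairs (equal-sign percentage)."""
    if len(pairs) == 0:
        raise ValidationError("no polarity pairs supplied")
    a, b = _polarity_arrays(pairs)
    conc = int(np.count_nonzero(a == b))
    disc = int(a.size - conc)
    return ConcordanceResult(
        n_concordant=conc,
        n_discordant=disc,
        percent_concordant=100.0 * conc / a.size,
        pairs=tuple((int(x), int(y)) for x, y in zip(a, b)),
    )


def surrogate_concordance_test(
    pairs: Sequence,
    n_surrogates: int = DEFAULT_N_SURROGATES,
    rng=None,
) -> SurrogateTest:
    """Monte-Carlo permutation test of polarity concordance.

    Each of ``n_surrogates`` surrogates re-pairs drug-1 polarities with an
    independent uniform permutation of the drug-2 polarities; the p-value is
    ``(1 + #{surrogate ≥ observed}) / (n_surrogates + 1)``.
    """
    if len(pairs) < 2:
        raise ValidationError("surrogate test requires at least 2 pairs")
    a, b = _polarity_arrays(pairs)
    observed = 100.0 * np.count_nonzero(a == b) / a.size
    if np.all(a == a[0]) and np.all(b == b[0]):
        warnings.warn(
            "all polarities identical in both drugs: surrogate test is degenerate (p=1)",
            stacklevel=2,
        )
    rng = as_rng(rng)
    perms = rng.permuted(np.tile(b, (n_surrogates, 1)), axis=1)
    surr = 100.0 * np.count_nonzero(perms == a, axis=1) / a.size
    p = (1.0 + np.count_nonzero(surr >= observed - 1e-12)) / (n_surrogates + 1.0)
    return SurrogateTest(
        observed_percent=float(observed),
        surrogate_percents=surr,
        p_value=float(p),
        n_surrogates=n_surrogates,
    )


def exhaustive_concordance_test(pairs: Sequence) -> float:
    """Exact permutation p-value by full enumeration (small inputs only).

    ``P(surrogate concordance ≥ observed)`` over all n! pairings; the
    independent reference for the Monte-Carlo test.
    """
    a, b = _polarity_arrays(pairs)
    if a.size > 8:
        raise ValidationError("exhaustive enumeration limited to ≤8 pairs")
    observed = np.count_nonzero(a == b)
    hits = total = 0
    for perm in permutations(b.tolist()):
        total += 1
        if np.count_nonzero(a == np.array(perm)) >= observed:
            hits += 1
    return hits / total


def response_correlation(
    delta_f_drug1: Sequence[float], delta_f_drug2: Sequence[float]
) -> tuple[float, float, int, float]:
    """Pearson correlation of paired response magnitudes.

    Returns ``(r, t, dof, p)`` with ``t = r·sqrt(n−2)/sqrt(1−r²)`` and
    ``dof = n − 2`` (two-sided p).
    """
    x = np.asarray(delta_f_drug1, dtype=float)
    y = np.asarray(delta_f_drug2, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired magnitudes must have equal length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in one of the response lists")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    dof = x.size - 2
    if abs(r) >= 1.0:
        return r, np.inf if r > 0 else -np.inf, dof, 0.0
    t = r * np.sqrt(dof) / np.sqrt(1.0 - r * r)
    from scipy import stats

    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(t), dof, float(p)
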