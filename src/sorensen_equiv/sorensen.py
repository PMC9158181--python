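"""Sorensen-Dice dissimilarity, its estimator and delta-method variance.

The dissimilarity between two feature lists, measured on the joint
law of term enrichment, is

    d_S(p) = 1 - 2 p11 / (2 p11 + p10 + p01),

which deliberately ignores the double-negative probability ``p00``:
terms enriched in neither list carry no information about similarity
and their count can be inflated at will by enlarging the term universe.
The scaled estimator ``sqrt(n) (d_S(p_hat) - d_S(p))`` is asymptotically
normal with a variance obtained by the delta method,

    sigma_S^2 = 4 p11 (p01 + p10) (p11 + p01 + p10) / (2 p11 + p01 + p10)^4.

Everything here is written against plain floats/arrays so the simulation
and bootstrap layers can evaluate the same formulas vectorized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .contingency import EnrichmentContingencyTable, JointEnrichmentProbs, estimate_probs

__all__ = [
    "UndefinedSorensenError",
    "SorensenEstimate",
    "sorensen_dissimilarity",
    "asymptotic_variance",
    "sorensen_estimate",
    "confidence_interval",
]


class UndefinedSorensenError(ValueError):
    """The Sorensen-Dice statistic cannot be formed for this input.

    Raised when ``p11 = p01 = p10 = 0`` (no enrichment anywhere, d_S has a
    0/0 form) and, in the testing routes, whenever the studentized
    statistic is undefined because ``sigma_hat = 0`` (``n11 = 0`` or
    ``n01 + n10 = 0``).  A distinct type so that simulation and bootstrap
    layers can catch it and decrement their effective replicate counts.
    """


def _unpack(p) -> tuple[float, float, float]:
    if isinstance(p, JointEnrichmentProbs):
        return p.p11, p.p01, p.p10
    p11, p01, p10 = p
    return float(p11), float(p01), float(p10)


def sorensen_dissimilarity(p) -> float:
    """d_S(p) = 1 - 2 p11 / (2 p11 + p10 + p01), in [0, 1].

    ``p`` may be a :class:`JointEnrichmentProbs` or a ``(p11, p01, p10)``
    triple; ``p00`` never enters the computation.
    """
    p11, p01, p10 = _unpack(p)
    denom = 2.0 * p11 + p01 + p10
    if denom <= 0.0:
        raise UndefinedSorensenError(
            "d_S undefined: p11 = p01 = p10 = 0 (no enrichment in either list)"
        )
    return 1.0 - 2.0 * p11 / denom


def asymptotic_variance(p) -> float:
    """Delta-method variance of sqrt(n) d_S(p_hat) (per-sqrt(n) scale)."""
    p11, p01, p10 = _unpack(p)
    u = p01 + p10
    denom = 2.0 * p11 + u
    if denom <= 0.0:
        raise UndefinedSorensenError(
            "sigma_S^2 undefined: p11 = p01 = p10 = 0"
        )
    return 4.0 * p11 * u * (p11 + u) / denom**4


@dataclass(frozen=True)
class SorensenEstimate:
    """Point estimate of d_S with its estimated asymptotic spread.

    ``sigma_hat`` is on the per-sqrt(n) scale: the standard error of
    ``d_hat`` is ``sigma_hat / sqrt(n)``.  ``degenerate`` flags tables
    with ``sigma_hat = 0`` (n11 = 0 or n01 + n10 = 0), on which the
    studentized statistic -- and hence any test -- is undefined.
    """

    d_hat: float
    sigma_hat: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_hat <= 1.0):
            raise ValueError(f"d_hat={self.d_hat} outside [0, 1]")
        if self.sigma_hat < 0.0:
            raise ValueError("sigma_hat must be >= 0")

    @property
    def se(self) -> float:
        return self.sigma_hat / math.sqrt(self.n)

    @property
    def degenerate(self) -> bool:
        return self.sigma_hat == 0.0


def sorensen_estimate(table: EnrichmentContingencyTable) -> SorensenEstimate:
    """Plug-in estimate of d_S and sigma_S from a contingency table.

    Raises :class:`UndefinedSorensenError` when all of n11, n10, n01 are
    zero.  Tables with n11 = 0 (d_hat = 1) or n10 + n01 = 0 (d_hat = 0)
    yield a flagged degenerate estimate with ``sigma_hat = 0``.
    """
    if table.n11 + table.n10 + table.n01 == 0:
        raise UndefinedSorensenError(
            "all enrichment cells are zero: d_S is a 0/0 form"
        )
    p_hat = estimate_probs(table)
    d_hat = sorensen_dissimilarity(p_hat)
    sigma_hat = math.sqrt(asymptotic_variance(p_hat))
    return SorensenEstimate(d_hat=d_hat, sigma_hat=sigma_hat, n=table.n)


def confidence_interval(
    est: SorensenEstimate, alpha: float = 0.05, sided: str = "two", clip: bool = False
) -> tuple[float, float]:
    """Normal-theory confidence interval for d_S at level 1 - alpha.

    ``sided="two"`` gives ``d_hat -/+ z_{1-alpha/2} * se``; ``sided="one"``
    gives the upper-limit interval ``[0, d_hat + z_{1-alpha} * se]`` used
    by the equivalence test.  Limits are reported unclipped by default
    (the equivalence decision compares the upper limit with d0 on the
    real line); pass ``clip=True`` for a display variant clipped to
    [0, 1].  A degenerate estimate collapses to the point ``[d_hat, d_hat]``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    se = est.se
    if sided == "two":
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        lo, hi = est.d_hat - z * se, est.d_hat + z * se
    elif sided == "one":
        z = sps.norm.ppf(1.0 - alpha)
        lo, hi = 0.0, est.d_hat + z * se
    else:
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    if clip:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return lo, hi


# -- vectorized kernels shared with the bootstrap and simulation layers ----


def _dissimilarity_array(n11, n01, n10):
    """Vectorized d_S from integer cell counts; 0/0 cells return nan."""
    n11 = np.asarray(n11, dtype=float)
    n01 = np.asarray(n01, dtype=float)
    n10 = np.asarray(n10, dtype=float)
    denom = 2.0 * n11 + n01 + n10
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, 1.0 - 2.0 * n11 / denom, np.nan)


def _sigma_array(p11, p01, p10):
    """Vectorized sigma_S from cell probabilities; undefined cells -> nan."""
    p11 = np.asarray(p11, dtype=float)
    u = np.asarray(p01, dtype=float) + np.asarray(p10, dtype=float)
    denom = 2.0 * p11 + u
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(denom > 0, 4.0 * p11 * u * (p11 + u) / denom**4, np.nan)
    return np.sqrt(var)
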