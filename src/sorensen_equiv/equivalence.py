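"""Equivalence (dissimilarity-irrelevance) test, normal flavour.

The hypothesis pair is

    H0: d_S(p) >= d0        (relevant dissimilarity)
    H1: d_S(p) <  d0        (irrelevant dissimilarity, "equivalence")

for a user-chosen irrelevance limit d0.  By the interval-inclusion
principle, H0 is rejected at level alpha when the one-sided 1 - alpha
upper confidence limit d_u falls below d0; equivalently when the
p-value Phi(sqrt(n) (d_hat - d0) / sigma_hat) is at most alpha.  Both
decisions are derived from the same studentized statistic so they can
never disagree.

d0 itself is always an arbitrary choice, but it can be motivated by a
lower bound rho_0 on the enrichment-concordance ratio: with
rho = 2 p11 / (p01 + p10) ("double" convention, mirroring the double
counting of p11 in the Sorensen-Dice index), d_S = 1 / (1 + rho); with
rho = p11 / (p01 + p10) ("single"), d_S = 1 / (1 + 2 rho).  The
bioequivalence-inspired ratios 10/8 and 10/9 then map to the limits
0.4444 / 0.4737 (double) and 0.2857 / 0.3103 (single).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy import stats as sps

from .contingency import EnrichmentContingencyTable
from .sorensen import SorensenEstimate, UndefinedSorensenError, sorensen_estimate

__all__ = [
    "EquivalenceResult",
    "equivalence_test_normal",
    "d0_from_rho",
    "rho_from_d0",
    "p11_for_target",
]


@dataclass(frozen=True)
class EquivalenceResult:
    """Outcome of one equivalence test (either flavour).

    ``reject=True`` establishes equivalence up to ``d0``.  ``boot_meta``
    is empty for the normal flavour and carries ``(B_requested,
    B_effective, seed)`` for the bootstrap one.
    """

    d0: float
    alpha: float
    d_hat: float
    se: float
    d_upper: float
    p_value: float
    reject: bool
    n: int
    method: str = "normal"
    boot_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "d0": self.d0,
            "alpha": self.alpha,
            "d_hat": self.d_hat,
            "se": self.se,
            "d_upper": self.d_upper,
            "p_value": self.p_value,
            "reject": bool(self.reject),
            "n": self.n,
            "method": self.method,
        }
        if self.boot_meta:
            out["boot_meta"] = dict(self.boot_meta)
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _validate_test_args(d0: float, alpha: float) -> None:
    if not 0.0 < d0 < 1.0:
        raise ValueError(f"equivalence limit d0 must be in (0, 1), got {d0}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"significance level alpha must be in (0, 1), got {alpha}")


def _require_studentizable(est: SorensenEstimate) -> None:
    if est.degenerate:
        raise UndefinedSorensenError(
            "studentized statistic undefined: sigma_hat = 0 "
            "(n11 = 0 or n10 + n01 = 0)"
        )


def equivalence_test_normal(
    table: EnrichmentContingencyTable, d0: float, alpha: float = 0.05
) -> EquivalenceResult:
    """Asymptotic-normal equivalence test of H0: d_S >= d0.

    The p-value is ``Phi(sqrt(n) (d_hat - d0) / sigma_hat)`` and the
    reported upper limit is ``d_hat + z_{1-alpha} * sigma_hat / sqrt(n)``;
    reject iff ``p_value <= alpha``.
    """
    _validate_test_args(d0, alpha)
    est = sorensen_estimate(table)
    _require_studentizable(est)
    t_obs = math.sqrt(est.n) * (est.d_hat - d0) / est.sigma_hat
    p_value = float(sps.norm.cdf(t_obs))
    z = float(sps.norm.ppf(1.0 - alpha))
    d_upper = est.d_hat + z * est.se
    return EquivalenceResult(
        d0=d0,
        alpha=alpha,
        d_hat=est.d_hat,
        se=est.se,
        d_upper=d_upper,
        p_value=p_value,
        reject=p_value <= alpha,
        n=est.n,
        method="normal",
    )


def d0_from_rho(rho: float, convention: str = "double") -> float:
    """Equivalence limit implied by a concordance-ratio lower bound.

    ``convention="double"``: rho = 2 p11 / (p01 + p10), d0 = 1 / (1 + rho).
    ``convention="single"``: rho = p11 / (p01 + p10), d0 = 1 / (1 + 2 rho).
    """
    if rho <= 0.0:
        raise ValueError(f"rho must be positive, got {rho}")
    if convention == "double":
        return 1.0 / (1.0 + rho)
    if convention == "single":
        return 1.0 / (1.0 + 2.0 * rho)
    raise ValueError(f"convention must be 'double' or 'single', got {convention!r}")


def rho_from_d0(d0: float, convention: str = "double") -> float:
    """Exact inverse of :func:`d0_from_rho`."""
    if not 0.0 < d0 < 1.0:
        raise ValueError(f"d0 must be in (0, 1), got {d0}")
    if convention == "double":
        return (1.0 - d0) / d0
    if convention == "single":
        return (1.0 - d0) / (2.0 * d0)
    raise ValueError(f"convention must be 'double' or 'single', got {convention!r}")


def p11_for_target(dS: float, p01: float, p10: float) -> float:
    """Joint-enrichment probability achieving a target dissimilarity.

    Solves ``d_S(p11, p01, p10) = dS`` for ``p11``:
    ``p11 = (1 - dS) (p10 + p01) / (2 dS)``.  Used to place simulation
    scenarios exactly on (or off) the equivalence boundary.
    """
    if not 0.0 < dS <= 1.0:
        raise ValueError(f"target dissimilarity must be in (0, 1], got {dS}")
    u = p01 + p10
    if u <= 0.0:
        raise ValueError("p01 + p10 must be positive")
    p11 = (1.0 - dS) * u / (2.0 * dS)
    if p11 + u > 1.0 + 1e-12:
        raise ValueError(
            f"infeasible scenario: p11={p11:.6g} with p01={p01}, p10={p10} "
            f"sums above 1"
        )
    return p11
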