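"""Multi-list equivalence testing with family-wise error control.

With s feature lists one may test all h = s(s-1)/2 pairs, or the s-1
comparisons against a designated reference list.  Raw p-values from the
chosen test flavour are adjusted by Holm's step-down (the default; a
uniform improvement over Bonferroni that still controls the FWER under
arbitrary dependence) or by Benjamini-Hochberg for large families.
Pairs on which the Sorensen statistic is undefined are flagged as not
testable and excluded from the family size h.

The Mantel permutation test for correlating two triangular matrices of
test outputs (e.g. upper confidence limits from two different methods
over the same lists) also lives here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bootstrap import equivalence_test_boot
from .contingency import EnrichmentProfile, build_table
from .equivalence import equivalence_test_normal
from .sorensen import UndefinedSorensenError

__all__ = ["PairwiseEquivalenceMatrix", "pairwise_tests", "mantel_correlation"]

_ADJUST_METHODS = {"holm": "holm", "bh": "fdr_bh", "none": None}


@dataclass
class PairwiseEquivalenceMatrix:
    """All pairwise equivalence-test results over a set of lists."""

    list_ids: list
    results: pd.DataFrame  # one row per testable ordered pair (i < j)
    not_testable: list  # pairs excluded because the statistic was undefined
    d0: float
    alpha: float
    method: str
    adjust: str

    @property
    def h(self) -> int:
        """Family size: the number of testable comparisons."""
        return len(self.results)

    def matrix(self, column: str = "d_upper") -> pd.DataFrame:
        """Square symmetric matrix of one result column (diagonal NaN)."""
        mat = pd.DataFrame(
            np.nan, index=self.list_ids, columns=self.list_ids, dtype=float
        )
        for row in self.results.itertuples():
            mat.at[row.list_1, row.list_2] = getattr(row, column)
            mat.at[row.list_2, row.list_1] = getattr(row, column)
        return mat

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _adjust(p_values: np.ndarray, how: str) -> np.ndarray:
    if how not in _ADJUST_METHODS:
        raise ValueError(f"adjust must be one of {sorted(_ADJUST_METHODS)}, got {how!r}")
    if _ADJUST_METHODS[how] is None or p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method=_ADJUST_METHODS[how])[1]


def pairwise_tests(
    profile: EnrichmentProfile,
    d0: float,
    alpha: float = 0.05,
    method: str = "normal",
    mode: str = "all-pairs",
    ref: str | None = None,
    adjust: str = "holm",
    B: int = 10000,
    seed=None,
) -> PairwiseEquivalenceMatrix:
    """Equivalence-test every selected pair of lists in a profile.

    ``mode="all-pairs"`` tests the h = s(s-1)/2 unordered pairs;
    ``mode="vs-reference"`` tests the s-1 pairs against ``ref``.  The
    reject flags are derived from the adjusted p-values (``p_adj <= alpha``).
    """
    lists = profile.list_ids
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    if mode == "all-pairs":
        pairs = list(itertools.combinations(lists, 2))
    elif mode == "vs-reference":
        if ref not in lists:
            raise ValueError(f"reference list {ref!r} not among {lists}")
        pairs = [(ref, other) for other in lists if other != ref]
    else:
        raise ValueError(f"mode must be 'all-pairs' or 'vs-reference', got {mode!r}")
    if method not in ("normal", "bootstrap"):
        raise ValueError(f"method must be 'normal' or 'bootstrap', got {method!r}")

    rng = np.random.default_rng(seed)
    rows, not_testable = [], []
    for a, b in pairs:
        table = build_table(profile, a, b)
        try:
            if method == "normal":
                res = equivalence_test_normal(table, d0, alpha)
            else:
                res = equivalence_test_boot(table, d0, alpha, B=B, seed=rng)
        except UndefinedSorensenError as exc:
            not_testable.append({"list_1": a, "list_2": b, "reason": str(exc)})
            continue
        rows.append(
            {
                "list_1": a,
                "list_2": b,
                "n": res.n,
                "d_hat": res.d_hat,
                "se": res.se,
                "d_upper": res.d_upper,
                "p_raw": res.p_value,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["list_1", "list_2", "n", "d_hat", "se", "d_upper", "p_raw"]
    )
    frame["p_adj"] = _adjust(frame["p_raw"].to_numpy(dtype=float), adjust)
    frame["reject"] = frame["p_adj"] <= alpha
    return PairwiseEquivalenceMatrix(
        list_ids=lists,
        results=frame,
        not_testable=not_testable,
        d0=d0,
        alpha=alpha,
        method=method,
        adjust=adjust,
    )


def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    idx = np.tril_indices(mat.shape[0], k=-1)
    return mat[idx]


def mantel_correlation(
    X, Y, permutations: int = 999, seed=None, exact: bool = False
) -> tuple[float, float]:
    """Mantel permutation test between two triangular test-output matrices.

    ``X`` and ``Y`` are square symmetric s x s matrices over the same
    lists in the same order (diagonals ignored).  Returns the Pearson
    correlation of the vectorized lower triangles and a two-sided
    permutation p-value obtained by relabelling the lists of ``Y``:
    ``(#{|r_perm| >= |r_obs|} + 1) / (permutations + 1)`` for random
    permutations, or the exact proportion over all s! relabelings when
    ``exact=True`` (small s only).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("X and Y must be square matrices of identical shape")
    s = X.shape[0]
    if s < 3:
        raise ValueError("need at least three lists for a Mantel test")
    x = _lower_triangle(X)
    y = _lower_triangle(Y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedSorensenError(
            "Mantel correlation undefined: a matrix is constant"
        )
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if exact:
        perms = list(itertools.permutations(range(s)))
        hits = 0
        for perm in perms:
            idx = np.array(perm)
            r_perm = np.corrcoef(x, _lower_triangle(Y[np.ix_(idx, idx)]))[0, 1]
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                hits += 1
        return r_obs, hits / len(perms)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(s)
        y_perm = _lower_triangle(Y[np.ix_(perm, perm)])
        r_perm = np.corrcoef(x, y_perm)[0, 1]
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p_value = (hits + 1) / (permutations + 1)
    return r_obs, p_value
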