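import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sorensen_equiv import (
    EnrichmentProfile,
    UndefinedSorensenError,
    mantel_correlation,
    pairwise_tests,
)
from sorensen_equiv.multilist import holm_adjust


def make_profile(rng, n_terms=300, lists=("a", "b", "c", "d"), q=0.5):
    cols = {name: rng.binomial(1, q, size=n_terms).tolist() for name in lists}
    return EnrichmentProfile.from_columns(
        [f"t{i}" for i in range(n_terms)], cols
    )


class TestHolm:
    def test_textbook_example(self):
        adjusted = holm_adjust([0.01, 0.02, 0.04])
        assert adjusted == pytest.approx([0.03, 0.04, 0.04], abs=1e-12)
        assert (adjusted <= 0.05).all()

    def test_single_test_unchanged(self):
        assert holm_adjust([0.031])[0] == pytest.approx(0.031, abs=1e-15)

    def test_all_ones_reject_nothing(self):
        assert (holm_adjust([1.0, 1.0, 1.0]) > 0.05).all()

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_dominance_chain(self, p_values):
        """Bonferroni rejections are a subset of Holm's, which are a subset
        of the unadjusted rejections, at any common level."""
        alpha = 0.05
        p = np.asarray(p_values)
        h = len(p)
        bonf = np.minimum(p * h, 1.0) <= alpha
        holm = holm_adjust(p) <= alpha
        raw = p <= alpha
        assert (~bonf | holm).all()  # bonf => holm
        assert (~holm | raw).all()  # holm => raw
        # adjusted >= raw and monotone in raw-p order
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPairwiseTests:
    def test_all_pairs_family_size(self, rng):
        profile = make_profile(rng)
        result = pairwise_tests(profile, d0=0.5, alpha=0.05)
        assert result.h == 6
        assert (result.results["p_adj"] >= result.results["p_raw"] - 1e-15).all()
        assert (result.results["reject"] == (result.results["p_adj"] <= 0.05)).all()

    def test_vs_reference_mode(self, rng):
        profile = make_profile(rng)
        result = pairwise_tests(profile, d0=0.5, mode="vs-reference", ref="a")
        assert result.h == 3
        assert set(result.results["list_1"]) == {"a"}
        with pytest.raises(ValueError, match="reference"):
            pairwise_tests(profile, d0=0.5, mode="vs-reference", ref="zz")

    def test_undefined_pairs_flagged_and_excluded(self, rng):
        profile = make_profile(rng, lists=("a", "b"))
        frame = profile.to_frame()
        frame["z"] = 0  # never enriched: pairs with z are untestable
        profile = EnrichmentProfile(frame)
        result = pairwise_tests(profile, d0=0.5)
        assert result.h == 1
        assert len(result.not_testable) == 2
        assert {(d["list_1"], d["list_2"]) for d in result.not_testable} == {
            ("a", "z"), ("b", "z"),
        }

    def test_bootstrap_method_deterministic(self, rng):
        profile = make_profile(rng, n_terms=200, lists=("a", "b", "c"))
        r1 = pairwise_tests(profile, d0=0.5, method="bootstrap", B=300, seed=42)
        r2 = pairwise_tests(profile, d0=0.5, method="bootstrap", B=300, seed=42)
        assert r1.results.equals(r2.results)

    def test_square_matrix_export(self, rng):
        profile = make_profile(rng)
        result = pairwise_tests(profile, d0=0.5)
        mat = result.matrix("d_upper")
        assert mat.shape == (4, 4)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)


class TestMantel:
    @staticmethod
    def symmetric(rng, s):
        m = rng.normal(size=(s, s))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        return m

    def test_identity_and_anti_identity(self, rng):
        X = self.symmetric(rng, 5)
        r, _ = mantel_correlation(X, X, permutations=99, seed=1)
        assert r == pytest.approx(1.0, abs=1e-12)
        r, _ = mantel_correlation(X, -X, permutations=99, seed=1)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_exact_p_matches_brute_force(self, rng):
        """Exhaustive enumeration over the 24 relabelings of 4 lists."""
        X = self.symmetric(rng, 4)
        Y = self.symmetric(rng, 4)
        r_obs, p_exact = mantel_correlation(X, Y, exact=True)

        # independent brute-force oracle
        idx = np.tril_indices(4, k=-1)
        x = X[idx]
        hits = 0
        perms = list(itertools.permutations(range(4)))
        for perm in perms:
            P = np.asarray(perm)
            yp = Y[np.ix_(P, P)][idx]
            r = np.corrcoef(x, yp)[0, 1]
            if abs(r) >= abs(r_obs) - 1e-12:
                hits += 1
        assert p_exact == pytest.approx(hits / math.factorial(4), abs=1e-15)

    def test_symmetric_in_arguments(self, rng):
        X = self.symmetric(rng, 6)
        Y = self.symmetric(rng, 6)
        r_xy, _ = mantel_correlation(X, Y, permutations=49, seed=2)
        r_yx, _ = mantel_correlation(Y, X, permutations=49, seed=2)
        assert r_xy == pytest.approx(r_yx, abs=1e-12)

    def test_invariant_under_common_relabeling(self, rng):
        X = self.symmetric(rng, 6)
        Y = self.symmetric(rng, 6)
        perm = rng.permutation(6)
        r1, _ = mantel_correlation(X, Y, permutations=9, seed=3)
        r2, _ = mantel_correlation(
            X[np.ix_(perm, perm)], Y[np.ix_(perm, perm)], permutations=9, seed=3
        )
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_matrix_raises(self, rng):
        X = self.symmetric(rng, 4)
        with pytest.raises(UndefinedSorensenError):
            mantel_correlation(X, np.ones((4, 4)), permutations=9)

    def test_too_few_lists_rejected(self):
        with pytest.raises(ValueError):
            mantel_correlation(np.zeros((2, 2)), np.zeros((2, 2)))
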