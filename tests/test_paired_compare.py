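import itertools

import numpy as np
import pytest
from scipy import stats

from entroread.entropy_core import EntropySpectrum
from entroread.paired_compare import (
    paired_deltas,
    rank_auc,
    signed_rank_test,
    spearman_rho,
    youden_threshold,
)


def enumeration_signed_rank_p(deltas):
    """Full 2^n enumeration oracle for the two-sided exact signed-rank p.

    Zeros discarded, midranks on |d|, p = 2 * min(P(W+ <= w), P(W+ >= w))
    capped at 1, with W+ enumerated over every sign assignment.
    """
    nz = [d for d in deltas if d != 0]
    ranks = stats.rankdata(np.abs(nz))
    w_obs = ranks[np.asarray(nz) > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(nz))
    ]
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_auc(minor, guardian):
    wins = sum(1.0 if g > m else 0.5 if g == m else 0.0 for g in guardian for m in minor)
    return wins / (len(minor) * len(guardian))


def _spectrum(doc_id, grid, values):
    return EntropySpectrum(doc_id, tuple(grid), dict(zip(grid, values)))


class TestPairedDeltas:
    def test_identical_spectra_give_zero(self):
        grid = (0.0, 1.0)
        s = _spectrum("m", grid, (2.0, 1.5))
        deltas = paired_deltas({"p1": (s, _spectrum("g", grid, (2.0, 1.5)))})
        assert all(d.delta == 0.0 for d in deltas)

    def test_uniform_closed_form_gap(self):
        grid = (0.0, 0.5, 1.0)
        minor = _spectrum("m", grid, (2.0, 2.0, 2.0))  # uniform over 4
        guardian = _spectrum("g", grid, (3.0, 3.0, 3.0))  # uniform over 8
        deltas = paired_deltas({"p1": (minor, guardian)})
        assert [d.delta for d in deltas] == [1.0, 1.0, 1.0]

    def test_cardinality_17_pairs_21_alphas(self):
        grid = tuple(np.round(np.arange(0, 2.05, 0.1), 10))
        spectra = {
            f"p{k}": (_spectrum("m", grid, np.ones(21)), _spectrum("g", grid, np.ones(21)))
            for k in range(17)
        }
        assert len(paired_deltas(spectra)) == 357

    def test_mismatched_grids_listed(self):
        a = _spectrum("m", (0.0, 1.0), (1, 1))
        b = _spectrum("g", (0.0, 0.5), (1, 1))
        with pytest.raises(ValueError, match="p1"):
            paired_deltas({"p1": (a, b)})


class TestSignedRank:
    def test_all_positive_n5(self):
        res = signed_rank_test([1, 2, 3, 4, 5])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)
        assert (res.n_positive, res.n_negative, res.n_zero) == (5, 0, 0)

    def test_tied_pair_is_uninformative(self):
        res = signed_rank_test([1, -1])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_discard(self):
        res = signed_rank_test([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.n_zero == 1 and res.n_used == 5
        assert res.p_value == pytest.approx(0.0625, abs=1e-12)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="nonzero"):
            signed_rank_test([0.0, 0.0])

    def test_method_switches_to_normal_approx(self, rng):
        res = signed_rank_test(rng.normal(size=30))
        assert res.method == "normal_approx"

    def test_exact_matches_enumeration_with_zeros_and_ties(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 13))
            d = rng.integers(-3, 4, size=n).astype(float)
            if np.all(d == 0):
                continue
            assert signed_rank_test(d).p_value == pytest.approx(
                enumeration_signed_rank_p(d), abs=1e-12
            )

    def test_matches_scipy_in_tie_free_exact_regime(self, rng):
        d = np.round(rng.normal(size=14), 6)  # distinct |d| w.p. 1
        expected = stats.wilcoxon(d, method="exact").pvalue
        assert signed_rank_test(d).p_value == pytest.approx(expected, rel=1e-9)

    def test_sign_counts_partition_pairs(self, rng):
        d = rng.integers(-2, 3, size=17).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        res = signed_rank_test(d)
        assert res.n_positive + res.n_negative + res.n_zero == 17


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([1, 2, 3], [4, 5, 6]) == 1.0

    def test_identical_lists(self):
        assert rank_auc([1, 2, 3], [1, 2, 3]) == 0.5

    def test_tied_example(self):
        assert rank_auc([1, 2, 5], [3, 4, 5]) == pytest.approx(6.5 / 9)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(200):
            m = rng.integers(0, 10, size=int(rng.integers(1, 31))).astype(float)
            g = rng.integers(0, 10, size=int(rng.integers(1, 31))).astype(float)
            assert rank_auc(m, g) == pytest.approx(brute_force_auc(m, g), abs=1e-12)

    def test_complement_and_monotone_invariance(self, rng):
        for _ in range(50):
            m = rng.normal(size=8)
            g = rng.normal(size=11)
            assert rank_auc(m, g) + rank_auc(g, m) == pytest.approx(1.0, abs=1e-12)
            f = lambda x: np.exp(3 * x) + 1  # noqa: E731 strictly increasing
            assert rank_auc(f(m), f(g)) == pytest.approx(rank_auc(m, g), abs=1e-12)


class TestYouden:
    def test_separated_midpoint(self):
        roc = youden_threshold([1, 2, 3], [4, 5, 6])
        assert (roc.threshold, roc.sensitivity, roc.specificity) == (3.5, 1.0, 1.0)
        assert roc.auc == 1.0

    def test_identical_lists_degenerate(self):
        roc = youden_threshold([1, 2, 3], [1, 2, 3])
        assert roc.sensitivity + roc.specificity == pytest.approx(1.0)
        assert roc.threshold == -np.inf  # lowest threshold on J ties

    def test_matches_exhaustive_scan(self, rng):
        def oracle(m, g):
            pooled = np.unique(np.concatenate([m, g]))
            cands = np.concatenate([[-np.inf], (pooled[:-1] + pooled[1:]) / 2, [np.inf]])
            best = max(
                (np.mean(g >= t) + np.mean(m < t) - 1, -t) for t in cands
            )
            return best[0], -best[1]

        for _ in range(50):
            m = rng.integers(0, 8, size=9).astype(float)
            g = rng.integers(2, 10, size=7).astype(float)
            j_best, t_best = oracle(m, g)
            roc = youden_threshold(m, g)
            assert roc.sensitivity + roc.specificity - 1 == pytest.approx(j_best, abs=1e-12)
            assert roc.threshold == t_best


class TestSpearman:
    def test_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(1 - 6 * 4 / (4 * 15), abs=1e-12)  # 0.6

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman_rho([1, 2], [2, 1])
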