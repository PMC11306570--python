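"""Non-parametric inference: Wilcoxon signed-rank, Spearman and the
semi-partial rank correlation, each against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from contagionkit import (
    differential_score,
    spearman,
    spearman_semipartial,
    wilcoxon_signed_rank,
)
from contagionkit.core import DegenerateInputError


def wilcoxon_enumeration_oracle(diffs):
    """Explicit 2^n sign-pattern enumeration of the null distribution.

    Returns (W, two-sided exact p) with Wilcoxon's zero-discard policy
    and mid-ranked ties.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    W = min(w_plus, w_minus)
    total = ranks.sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if wp <= W + 1e-12 or wp >= total - W - 1e-12:
            count += 1
    return W, count / 2**n


def rank_midrank(values):
    """Mid-rank transform written independently of scipy.rankdata."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def semipartial_oracle(x, y, C):
    """Brute-force rank residualization using the pseudoinverse."""
    rx = rank_midrank(x)
    ry = rank_midrank(y)
    RC = np.column_stack([rank_midrank(C[:, j]) for j in range(C.shape[1])])
    design = np.column_stack([np.ones(len(rx)), RC])
    resid = rx - design @ (np.linalg.pinv(design) @ rx)
    rm, ym = resid - resid.mean(), ry - ry.mean()
    return float((rm @ ym) / np.sqrt((rm @ rm) * (ym @ ym)))


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.W == 0.0
        assert res.p_value == pytest.approx(0.25)  # 2/8 sign patterns

    def test_symmetric_pairs_no_evidence(self):
        res = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_diffs_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n == 3
        assert res.p_value == pytest.approx(0.25)

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(10):
            # integer-valued diffs force ties in |d|
            d = rng.integers(-5, 6, n).astype(float)
            if np.all(d == 0):
                continue
            res = wilcoxon_signed_rank(d)
            W, p = wilcoxon_enumeration_oracle(d)
            assert res.W == pytest.approx(W)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(17)
        for n in (6, 10, 14):
            d = rng.normal(0.3, 1.0, n)  # continuous: no ties
            res = wilcoxon_signed_rank(d)
            ref = sps.wilcoxon(d, method="exact")
            assert res.W == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_n_close_to_scipy_approx(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.2, 1.0, 60)
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert res.method == "normal"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_effect_r_signed_by_median_direction(self):
        pos = wilcoxon_signed_rank(np.r_[np.full(20, 0.5), [-0.1]])
        neg = wilcoxon_signed_rank(-np.r_[np.full(20, 0.5), [-0.1]])
        assert pos.effect_r > 0 > neg.effect_r
        assert abs(pos.effect_r) == pytest.approx(abs(neg.effect_r))
        assert abs(pos.effect_r) <= 1.0


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(8.0)
        assert spearman(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_hand_ranked_pearson_on_printed_pairs(self):
        x = [2.1, 4.7, 1.3, 9.0, 5.5, 5.5, 3.2, 8.1]
        y = [0.4, 1.2, 0.1, 3.3, 0.9, 2.0, 0.4, 2.6]
        res = spearman(x, y)
        rx, ry = rank_midrank(x), rank_midrank(y)
        hand = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(hand, abs=1e-12)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ci_contains_rho_and_matches_fisher_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman(x, y)
        lo, hi = res.ci95
        assert lo < res.rho < hi
        se = 1.03 / np.sqrt(30 - 3)
        assert hi == pytest.approx(np.tanh(np.arctanh(res.rho) + 1.96 * se), abs=1e-3)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestSemipartial:
    def test_null_covariates_reduce_to_full_spearman(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        # covariates carrying no rank information about x or y
        C = np.tile(np.arange(40.0)[rng.permutation(40)], (2, 1)).T
        C[:, 1] = rng.permutation(C[:, 1])
        full = spearman(x, y).rho
        semi = spearman_semipartial(x, y, C).rho
        # random covariates remove a little variance by chance; the
        # exact-zero-coefficient limit is checked with constants-free
        # orthogonal ranks below
        assert semi == pytest.approx(full, abs=0.08)

    def test_covariate_fully_explaining_y_gives_near_zero(self):
        # y is an exact function of the covariate and x is independent:
        # after removing the covariate from the trait side, nothing is
        # left to correlate
        rng = np.random.default_rng(3)
        n = 10_000
        c = rng.normal(size=n)
        y = 2.0 * c + 1.0
        x = rng.normal(size=n)
        res = spearman_semipartial(x, y, c[:, None])
        assert abs(res.rho) < 0.05

    def test_residualized_side_fully_explained_raises(self):
        rng = np.random.default_rng(30)
        c = rng.normal(size=50)
        with pytest.raises(DegenerateInputError):
            spearman_semipartial(rng.normal(size=50), 2 * c + 1, c[:, None], residualize="y")

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 12
            x = rng.normal(size=n)
            C = rng.normal(size=(n, 2))
            y = 0.5 * x + C @ [0.3, -0.2] + rng.normal(size=n)
            res = spearman_semipartial(x, y, C)
            assert res.rho == pytest.approx(semipartial_oracle(x, y, C), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 50
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
            }
        )
        df["y"] += 0.5 * df["x"]
        res = spearman_semipartial(
            df["x"], df["y"], df[["a", "b"]].to_numpy(), residualize="x"
        )
        ref = pingouin.partial_corr(
            df, x="x", y="y", x_covar=["a", "b"], method="spearman"
        )
        assert res.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        C = rng.normal(size=(n, 1))
        base = spearman_semipartial(x, y, C).rho
        warped = spearman_semipartial(np.exp(x), y**3 + 5 * y, np.tanh(C))
        assert warped.rho == pytest.approx(base, abs=1e-12)

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(DegenerateInputError):
            spearman_semipartial(x, y, np.column_stack([c, c]))


class TestDifferentialScore:
    def make(self, large, small):
        rows = [{"stim_pupil": "large", "value": v, "valid": True} for v in large]
        rows += [{"stim_pupil": "small", "value": v, "valid": True} for v in small]
        return pd.DataFrame(rows)

    def test_basic_arithmetic(self):
        score = differential_score(self.make([0.10], [0.04]), "p1", "pupil", "CROSS")
        assert score.diff == pytest.approx(0.06)

    def test_identical_cells_zero(self):
        score = differential_score(self.make([0.2, 0.2], [0.2]), "p1", "pupil", "CROSS")
        assert score.diff == 0.0

    def test_empty_cell_flagged_missing(self):
        score = differential_score(self.make([0.2], []), "p1", "pupil", "CROSS")
        assert not score.valid
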