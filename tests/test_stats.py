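import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats as sps

from mzpanel.stats import (
    ROCComparison,
    chisq_2x2,
    chisq_gof,
    compare_independent_rocs,
    hanley_mcneil_se,
    mann_whitney_auc,
    two_sample_t,
)


def roc(auc, n1, n0):
    return SimpleNamespace(auc=auc, n_cases=n1, n_controls=n0)


class TestMannWhitneyAuc:
    def test_perfect(self):
        assert mann_whitney_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_reversed(self):
        assert mann_whitney_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1]) == 0.0

    def test_all_tied_half(self):
        assert mann_whitney_auc([5.0] * 8, [0, 1] * 4) == 0.5

    def test_three_quarters(self):
        # cases {2, 4}, controls {1, 3}: 3 of 4 pairs won
        assert mann_whitney_auc([2, 4, 1, 3], [1, 1, 0, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([1.0, 2.0], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle(self, seed):
        """Rank formula equals the direct pairwise-comparison definition."""
        rng = np.random.default_rng(seed)
        n1, n0 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
        scores = np.round(rng.normal(size=n1 + n0), 1)  # induce ties
        y = np.array([1] * n1 + [0] * n0)
        s1, s0 = scores[y == 1], scores[y == 0]
        wins = sum((a > b) + 0.5 * (a == b) for a in s1 for b in s0)
        assert mann_whitney_auc(scores, y) == pytest.approx(wins / (n1 * n0))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        y = (rng.random(30) > 0.5).astype(int)
        a1 = mann_whitney_auc(scores, y)
        a2 = mann_whitney_auc(np.exp(scores), y)
        assert a1 == pytest.approx(a2)


class TestHanleyMcNeilSe:
    def test_degenerate_auc_one(self):
        assert hanley_mcneil_se(1.0, 27, 36) == 0.0

    @pytest.mark.parametrize(
        "auc,n1,n0,expected",
        [
            (0.791, 27, 36, 0.0597),
            (0.738, 31, 53, 0.0587),
        ],
    )
    def test_reference_values(self, auc, n1, n0, expected):
        assert hanley_mcneil_se(auc, n1, n0) == pytest.approx(expected, abs=5e-5)

    @pytest.mark.parametrize(
        "auc,n1,n0", [(0.851, 27, 36), (0.830, 31, 53), (0.848, 27, 36), (0.811, 31, 53)]
    )
    def test_formula_oracle(self, auc, n1, n0):
        """Independent spelled-out transcription of the published formula."""
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
        assert hanley_mcneil_se(auc, n1, n0) == pytest.approx(math.sqrt(var), abs=1e-12)

    def test_decreases_with_n(self):
        assert hanley_mcneil_se(0.8, 100, 100) < hanley_mcneil_se(0.8, 20, 20)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            hanley_mcneil_se(1.2, 10, 10)
        with pytest.raises(ValueError):
            hanley_mcneil_se(0.8, 0, 10)

    @pytest.mark.parametrize("auc", [0.6, 0.75, 0.9])
    def test_within_15pct_of_bootstrap(self, auc):
        """Closed-form SE agrees with a stratified bootstrap of binormal scores."""
        rng = np.random.default_rng(11)
        n1 = n0 = 120
        d = math.sqrt(2) * sps.norm.ppf(auc)  # binormal shift giving this AUC
        s1 = rng.normal(d, 1, n1)
        s0 = rng.normal(0, 1, n0)
        scores = np.concatenate([s1, s0])
        y = np.array([1] * n1 + [0] * n0)
        a_hat = mann_whitney_auc(scores, y)
        boots = []
        for _ in range(300):
            b1 = rng.choice(s1, n1, replace=True)
            b0 = rng.choice(s0, n0, replace=True)
            boots.append(mann_whitney_auc(np.concatenate([b1, b0]), y))
        se_boot = float(np.std(boots, ddof=1))
        se_hm = hanley_mcneil_se(a_hat, n1, n0)
        assert se_hm == pytest.approx(se_boot, rel=0.15)


class TestCompareIndependentRocs:
    @pytest.mark.parametrize(
        "a1,n1a,n1n,a2,n2a,n2n,z,p",
        [
            (0.851, 27, 36, 0.830, 31, 53, 0.292, 0.770),
            (0.848, 27, 36, 0.811, 31, 53, 0.502, 0.616),
            (0.791, 27, 36, 0.738, 31, 53, 0.633, 0.527),
        ],
    )
    def test_reference_comparisons(self, a1, n1a, n1n, a2, n2a, n2n, z, p):
        cmp = compare_independent_rocs(roc(a1, n1a, n1n), roc(a2, n2a, n2n))
        assert cmp.z == pytest.approx(z, abs=1.5e-3)
        assert cmp.p == pytest.approx(p, abs=1.5e-3)
        assert cmp.conclusion == "accept_H0"

    def test_antisymmetry(self):
        r1, r2 = roc(0.9, 20, 30), roc(0.7, 25, 25)
        c12 = compare_independent_rocs(r1, r2)
        c21 = compare_independent_rocs(r2, r1)
        assert c12.z == pytest.approx(-c21.z)
        assert c12.p == pytest.approx(c21.p)

    def test_identical_rocs(self):
        r = roc(0.8, 20, 30)
        cmp = compare_independent_rocs(r, r)
        assert cmp.z == 0.0
        assert cmp.p == 1.0
        assert cmp.conclusion == "accept_H0"

    def test_large_difference_rejects(self):
        cmp = compare_independent_rocs(roc(0.95, 100, 100), roc(0.6, 100, 100))
        assert cmp.conclusion == "reject_H0"
        assert cmp.p < 1e-6

    def test_conclusion_threshold(self):
        c = ROCComparison(0.8, 0.7, 0.05, 0.05, z=1.0, p=0.049)
        assert c.conclusion == "reject_H0"
        c = ROCComparison(0.8, 0.7, 0.05, 0.05, z=1.0, p=0.051)
        assert c.conclusion == "accept_H0"


class TestChisqGof:
    def test_reference_value(self):
        chi2, df, p = chisq_gof([26, 5], [0.5, 0.5])
        assert chi2 == pytest.approx(14.23, abs=5e-3)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(chi2, 1))

    def test_exact_fit_zero(self):
        chi2, df, p = chisq_gof([50, 50], [0.5, 0.5])
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy(self):
        counts = [12, 7, 31]
        props = [0.2, 0.3, 0.5]
        chi2, df, p = chisq_gof(counts, props)
        ref = sps.chisquare(counts, f_exp=np.array(props) * sum(counts))
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            chisq_gof([10, 10], [0.6, 0.6])


class TestChisq2x2:
    def test_reference_value(self):
        chi2, df, p = chisq_2x2([[22, 16], [26, 5]])
        assert chi2 == pytest.approx(5.44, abs=5e-3)
        assert df == 1
        assert p < 0.05

    def test_independence_zero(self):
        chi2, _, p = chisq_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_uncorrected(self):
        t = [[13, 8], [5, 21]]
        chi2, _, p = chisq_2x2(t)
        ref = sps.chi2_contingency(t, correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_matches_scipy_yates(self):
        t = [[13, 8], [5, 21]]
        chi2, _, p = chisq_2x2(t, yates=True)
        ref = sps.chi2_contingency(t, correction=True)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_yates_never_larger(self):
        t = [[9, 3], [4, 11]]
        assert chisq_2x2(t, yates=True)[0] <= chisq_2x2(t)[0]

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2([[0, 0], [5, 5]])


class TestTwoSampleT:
    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 15), rng.normal(1, 2, 20)
        t, df, p = two_sample_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_pooled_variant(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=12)
        t, df, p = two_sample_t(x, y, welch=False)
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic)
        assert df == pytest.approx(20.0)

    def test_identical_constant_samples(self):
        t, df, p = two_sample_t([3.0, 3.0, 3.0], [3.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_distinct_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0], [2.0, 2.0])

    def test_null_type_one_error_rate(self):
        """Under the null, the Welch test rejects at ~alpha."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x, y = rng.normal(size=(2, 25))
            if two_sample_t(x, y)[2] < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.09
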