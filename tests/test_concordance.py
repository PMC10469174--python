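"""Agreement statistics: CCC, COV, Bland-Altman, McNemar, t tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import stilkit as sk
from tests.conftest import make_panel


def brute_force_ccc(x, y):
    """Term-by-term evaluation of Lin's definition with /n moments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((xi - mx) ** 2 for xi in x) / n
    sy2 = sum((yi - my) ** 2 for yi in y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


class TestLinsCCC:
    def test_perfect_agreement(self):
        r = sk.lins_ccc([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.estimate == pytest.approx(1.0)

    def test_worked_shifted_vectors(self):
        # biased (/n) moments: 2·66.667/(66.667+66.667+100) = 0.5714
        r = sk.lins_ccc([10, 20, 30], [20, 30, 40])
        assert r.estimate == pytest.approx(0.5714, abs=5e-5)

    def test_matches_brute_force_oracle(self, rng):
        x = rng.normal(20, 10, size=50)
        y = 0.8 * x + rng.normal(0, 5, size=50)
        assert sk.lins_ccc(x, y).estimate == pytest.approx(brute_force_ccc(x, y), abs=1e-12)

    def test_ci_brackets_estimate(self, rng):
        x = rng.uniform(0, 100, 40)
        y = x + rng.normal(0, 10, 40)
        r = sk.lins_ccc(x, y)
        assert r.ci_low <= r.estimate <= r.ci_high
        assert -1 <= r.ci_low and r.ci_high <= 1

    def test_both_constant_degenerate(self):
        with pytest.raises(sk.DegenerateStatisticError):
            sk.lins_ccc([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        with pytest.raises(sk.DegenerateStatisticError):
            sk.lins_ccc([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])

    @given(
        data=st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)), min_size=4, max_size=30
        ),
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_shift_and_scale_invariance_and_pearson_bound(self, data, shift, scale):
        x = np.array([a for a, _ in data])
        y = np.array([b for _, b in data])
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return
        ccc = sk.lins_ccc(x, y).estimate
        # common shift and common positive rescaling leave CCC unchanged
        assert sk.lins_ccc(scale * x + shift, scale * y + shift).estimate == pytest.approx(
            ccc, abs=1e-8
        )
        # |CCC| <= |Pearson r| (CCC = r·C_b with C_b in (0,1])
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r = stats.pearsonr(x, y).statistic
            assert abs(ccc) <= abs(r) + 1e-9


class TestPairwiseCCC:
    def test_identical_readers_concordant(self):
        panel = make_panel({"A": [1, 5, 9, 13.0], "B": [1, 5, 9, 13.0]})
        mat = sk.pairwise_ccc(panel)
        assert mat.loc["A", "B"].estimate == pytest.approx(1.0)
        assert mat.loc["A", "A"].estimate == 1.0

    def test_no_shared_slides_marked_unavailable(self):
        panel = make_panel({"A": [1, 2, 3, None, None, None], "B": [None, None, None, 4, 5, 6]})
        mat = sk.pairwise_ccc(panel)
        assert mat.loc["A", "B"] is None

    def test_composition_with_lins_ccc(self):
        panel = make_panel({"A": [10, 20, 30, 40.0], "B": [12, 18, 33, 39.0]})
        direct = sk.lins_ccc(panel["A"].to_numpy(), panel["B"].to_numpy())
        assert sk.pairwise_ccc(panel).loc["A", "B"].estimate == pytest.approx(direct.estimate)


class TestCovPerCase:
    def test_hand_computed_cov(self):
        panel = make_panel({"A": [10.0], "B": [20.0], "C": [30.0]})
        cov = sk.cov_per_case(panel)
        assert cov.per_slide.iloc[0] == pytest.approx(0.5)  # SD 10 / mean 20

    def test_equal_readers_zero(self):
        panel = make_panel({"A": [25.0, 0.0], "B": [25.0, 0.0]})
        cov = sk.cov_per_case(panel)
        assert (cov.per_slide == 0).all()  # all-equal and all-zero conventions

    def test_single_reader_slide_excluded_with_warning(self):
        panel = make_panel({"A": [10.0, 15.0], "B": [20.0, None]})
        with pytest.warns(UserWarning, match="excluded"):
            cov = sk.cov_per_case(panel)
        assert cov.n == 1


class TestBlandAltman:
    def test_identity_pairs(self):
        x = np.array([1.0, 5.0, 9.0, 2.0])
        r = sk.bland_altman(x, x)
        assert (r.mean_diff, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)

    def test_percentile_convention_on_integer_ladder(self):
        # d = 1..100, h = (n-1)p + 1 linear interpolation
        d = np.arange(1, 101, dtype=float)
        r = sk.bland_altman(d, np.zeros(100))
        assert r.loa_low == pytest.approx(3.475)
        assert r.loa_high == pytest.approx(97.525)

    def test_limits_bracket_central_mass(self, rng):
        d = rng.normal(0, 8, size=2000)
        r = sk.bland_altman(d, np.zeros(2000))
        inside = np.mean((d >= r.loa_low) & (d <= r.loa_high))
        assert abs(inside - 0.95) < 0.015


class TestMcNemar:
    def test_symmetric_counts_give_one(self):
        assert sk.mcnemar_test(5, 5) == pytest.approx(1.0)
        assert sk.mcnemar_test(0, 0) == 1.0

    def test_exact_binomial_closed_form(self):
        # 2·Σ_{k<=2} C(12,k)/2^12 = 158/4096
        assert sk.mcnemar_test(10, 2) == pytest.approx(158 / 4096)
        assert sk.mcnemar_test(10, 2) == pytest.approx(0.0386, abs=5e-5)

    def test_continuity_corrected_chi2_path(self):
        b, c = 100, 50
        stat = (abs(b - c) - 1) ** 2 / (b + c)
        assert sk.mcnemar_test(b, c) == pytest.approx(stats.chi2.sf(stat, 1))

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(1, 10))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_p_symmetric_and_monotone(self, b, c, shift):
        assert sk.mcnemar_test(b, c) == pytest.approx(sk.mcnemar_test(c, b))
        # at fixed b+c, widening |b−c| cannot increase p
        total = b + c
        lo, hi = min(b, c), max(b, c)
        if lo - shift >= 0:
            p_wider = sk.mcnemar_test(lo - shift, hi + shift)
            assert p_wider <= sk.mcnemar_test(b, c) + 1e-12


class TestMeanTests:
    def test_identical_groups(self):
        t, p = sk.mean_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_paired_differences_degenerate(self):
        with pytest.raises(sk.DegenerateStatisticError):
            sk.mean_tests([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0], paired=True)

    def test_two_sample_matches_independent_t_cdf(self, rng):
        x = rng.normal(10, 3, 20)
        y = rng.normal(12, 3, 25)
        t, p = sk.mean_tests(x, y)
        # independent pooled-variance computation + t CDF
        sp2 = ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1)) / (
            len(x) + len(y) - 2
        )
        t_manual = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        df = len(x) + len(y) - 2
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_manual), df), rel=1e-12)

    def test_paired_matches_one_sample_on_differences(self, rng):
        x = rng.normal(10, 3, 15)
        y = x + rng.normal(1, 2, 15)
        t, p = sk.mean_tests(x, y, paired=True)
        d = x - y
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_manual, rel=1e-12)


def test_chi_square_wrapper_matches_scipy():
    table = [[30, 10], [20, 40]]
    stat, p = sk.chi_square_test(table)
    ref = stats.chi2_contingency(np.array(table), correction=False)
    assert (stat, p) == (ref.statistic, ref.pvalue)
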