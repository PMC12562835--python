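from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ystrped.counting import compare_pair
from ystrped.rates import (
    ci_clopper_pearson,
    ci_wilson,
    compare_rates,
    estimate_rates,
    rates_from_counts,
    reconstruct_count,
    round_half_up,
)

from _oracles import fisher_two_sided
from conftest import make_pair


class TestRounding:
    @pytest.mark.parametrize(
        "value,ndigits,expected",
        [(0.0005, 3, 0.001), (0.0125, 3, 0.013), (0.0134, 3, 0.013), (60.05, 1, 60.1)],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected


class TestClopperPearson:
    @pytest.mark.parametrize("x,n", [(0, 10), (1, 10), (5, 5), (0, 1576), (21, 1576)])
    def test_matches_statsmodels_beta(self, x, n):
        lo, hi = ci_clopper_pearson(x, n)
        ref_lo, ref_hi = proportion_confint(x, n, alpha=0.05, method="beta")
        assert lo == pytest.approx(0.0 if x == 0 else ref_lo, abs=1e-12)
        assert hi == pytest.approx(1.0 if x == n else ref_hi, abs=1e-12)

    def test_boundaries(self):
        assert ci_clopper_pearson(0, 1576)[0] == 0.0
        assert ci_clopper_pearson(5, 5)[1] == 1.0

    def test_coverage_at_study_scale(self):
        """Exact intervals cover the true proportion at >= the nominal
        level over 2000 binomial draws at (N=1576, p=0.008)."""
        rng = np.random.default_rng(12345)
        n, p, reps = 1576, 0.008, 2000
        xs = rng.binomial(n, p, size=reps)
        lo = np.where(xs == 0, 0.0, stats.beta.ppf(0.025, xs, n - xs + 1))
        hi = np.where(xs == n, 1.0, stats.beta.ppf(0.975, xs + 1, n - xs))
        coverage = np.mean((lo <= p) & (p <= hi))
        mc_tol = 3 * np.sqrt(0.95 * 0.05 / reps)
        assert coverage >= 0.95 - mc_tol

    @pytest.mark.parametrize("x,n,alpha", [(-1, 10, 0.05), (11, 10, 0.05), (1, 0, 0.05), (1, 10, 0)])
    def test_preconditions(self, x, n, alpha):
        with pytest.raises(ValueError):
            ci_clopper_pearson(x, n, alpha)


class TestWilson:
    @pytest.mark.parametrize("x,n", [(0, 10), (13, 1576), (788, 1576), (30, 60)])
    def test_matches_statsmodels_score(self, x, n):
        lo, hi = ci_wilson(x, n)
        ref_lo, ref_hi = proportion_confint(x, n, alpha=0.05, method="wilson")
        assert lo == pytest.approx(max(ref_lo, 0.0), abs=1e-12)
        assert hi == pytest.approx(ref_hi, abs=1e-12)

    def test_zero_count_pins_lower_bound(self):
        assert ci_wilson(0, 10)[0] == 0.0

    def test_symmetric_about_half(self):
        lo, hi = ci_wilson(788, 1576)
        assert lo + hi == pytest.approx(1.0, abs=1e-12)

    def test_contains_point_estimate_and_narrower_than_exact(self):
        """Score intervals sit inside the exact interval across a grid of
        interior counts (checked empirically, N >= 30)."""
        for n in (30, 100, 500, 1576):
            for x in range(1, n, max(1, n // 17)):
                w_lo, w_hi = ci_wilson(x, n)
                c_lo, c_hi = ci_clopper_pearson(x, n)
                assert w_lo <= x / n <= w_hi
                assert (w_hi - w_lo) <= (c_hi - c_lo) + 1e-12

    def test_spec_interval_contains_reference_rate(self):
        lo, hi = ci_wilson(13, 1576)
        assert lo < 0.00825 < hi


class TestEstimateRates:
    def test_counts_and_meioses_summed(self, panel):
        pairs = [
            make_pair(panel, "F1", 6, {"DYS627": "20"}, {"DYS627": "22"}),
            make_pair(panel, "F2", 10, {"DYS627": "20"}, {"DYS627": "21"}),
            make_pair(panel, "F3", 4),
        ]
        comps = [compare_pair(p, panel) for p in pairs]
        rates = estimate_rates(comps, panel)
        by_locus = {r.locus: r for r in rates}
        est = by_locus["DYS627"]
        assert (est.x, est.N) == (3, 20)
        assert est.mu_hat == pytest.approx(0.15)
        assert all(r.N == 20 for r in rates)
        assert by_locus["DYS19"].x == 0

    def test_counts_only_mode_matches_direct_ci(self):
        (est,) = rates_from_counts({"DYS627": 21}, 1576)
        assert est.mu_hat == pytest.approx(21 / 1576)
        assert (est.ci_low, est.ci_high) == ci_clopper_pearson(21, 1576)
        assert est.mu_rounded == 0.013

    def test_empty_comparisons_error(self, panel):
        with pytest.raises(ValueError):
            estimate_rates([], panel)


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert compare_rates(5, 100, 5, 100).p_value == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        p = compare_rates(0, 10, 10, 10).p_value
        assert p == pytest.approx(fisher_two_sided(0, 10, 10, 0), rel=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x1=st.integers(0, 15), n1=st.integers(1, 15),
        x2=st.integers(0, 15), n2=st.integers(1, 15),
    )
    def test_enumeration_oracle_and_row_swap_invariance(self, x1, n1, x2, n2):
        x1, x2 = min(x1, n1), min(x2, n2)
        p = compare_rates(x1, n1, x2, n2).p_value
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(
            fisher_two_sided(x1, n1 - x1, x2, n2 - x2), rel=1e-9, abs=1e-12
        )
        assert p == pytest.approx(compare_rates(x2, n2, x1, n1).p_value, rel=1e-12)

    def test_reconstructed_reference_counts_flagged_approximate(self):
        x2 = reconstruct_count(0.010, 1000)
        assert x2 == 10
        comp = compare_rates(1, 1575, x2, 1000, approximate=True)
        assert comp.approximate
        # sensitivity: the reconstructed count is only precise to the
        # printed rate, so neighbouring counts shift p
        p_mid = comp.p_value
        p_lo = compare_rates(1, 1575, x2 - 1, 1000).p_value
        p_hi = compare_rates(1, 1575, x2 + 1, 1000).p_value
        assert p_lo != p_mid or p_hi != p_mid
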