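"""Pairwise ICI-Kt core: pair census, tau-b, tau_max, completeness, p-value."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kendalltau, norm

from icitau.core import (
    PairCounts,
    UndefinedCorrelationError,
    completeness,
    count_pairs_bruteforce,
    ici_kt_fast,
    mann_kendall_pvalue,
    tau_b_from_counts,
    tau_max,
)

NA = np.nan


class TestBruteForceCensus:
    @pytest.mark.parametrize(
        "x, y, perspective, expected",
        [
            # perfect concordance
            ([1, 2, 3], [4, 5, 6], "local", dict(n_concordant=3, n_discordant=0, n_tot=3)),
            # present-vs-missing comparisons carry ordering information
            ([1, 2, NA], [NA, 3, 2], "local", dict(n_concordant=2, n_discordant=1, n_tot=3)),
            # global keeps the both-missing point as a tie in both
            (
                [1, 2, NA, NA],
                [2, 3, NA, NA],
                "global",
                dict(n_concordant=5, n_discordant=0, n_xtie=1, n_ytie=1, n_tie_common=1, n_tot=6),
            ),
            # an observed tie in x
            ([1, 1, 2], [1, 2, 3], "local", dict(n_concordant=2, n_discordant=0, n_xtie=1, n_tot=3)),
        ],
    )
    def test_census_examples(self, x, y, perspective, expected):
        counts = count_pairs_bruteforce(x, y, perspective)
        for key, val in expected.items():
            assert getattr(counts, key) == val, key

    def test_local_removes_commonly_missing_points(self):
        local = count_pairs_bruteforce([1, 2, NA, NA], [2, 3, NA, NA], "local")
        assert local.n_tot == 1 and local.n_concordant == 1

    def test_length_errors(self):
        with pytest.raises(ValueError):
            count_pairs_bruteforce([1], [2])
        with pytest.raises(ValueError):
            count_pairs_bruteforce([1, 2], [1, 2, 3])

    def test_local_all_removed_is_degenerate(self):
        with pytest.raises(UndefinedCorrelationError):
            count_pairs_bruteforce([NA, NA, 1], [NA, NA, 2], "local")


class TestTauFormulas:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (PairCounts(3, 0, 0, 0, 0, 3), 1.0),
            (PairCounts(2, 1, 0, 0, 0, 3), 1 / 3),
            (PairCounts(2, 0, 1, 0, 0, 3), 2 / math.sqrt(6)),
        ],
    )
    def test_tau_b(self, counts, expected):
        assert tau_b_from_counts(counts) == pytest.approx(expected, abs=1e-15)

    def test_tau_b_degenerate(self):
        # all pairs tied in x
        with pytest.raises(UndefinedCorrelationError):
            tau_b_from_counts(PairCounts(0, 0, 3, 0, 0, 3))

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (PairCounts(6, 0, 0, 0, 0, 6), 1.0),
            (PairCounts(5, 0, 1, 1, 1, 6), 1.0),  # fully shared ties
            (PairCounts(4, 0, 1, 1, 0, 6), 4 / 5),
        ],
    )
    def test_tau_max(self, counts, expected):
        assert tau_max(counts) == pytest.approx(expected, abs=1e-15)


class TestCompleteness:
    def test_examples(self):
        assert completeness([1, 2, 3], [4, 5, 6]) == 1.0
        assert completeness([1, NA, 3, 4], [1, 2, NA, 4]) == 0.5
        assert completeness([NA, NA], [1, 2]) == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            completeness([], [])


class TestMannKendall:
    def test_no_tie_closed_form(self):
        # n=10, S=45: Var = 10*9*25/18 = 125
        counts = PairCounts(45, 0, 0, 0, 0, 45)
        z = 45 / math.sqrt(125)
        assert mann_kendall_pvalue(counts, 10) == pytest.approx(2 * norm.sf(z), rel=1e-12)
        assert mann_kendall_pvalue(counts, 10) == pytest.approx(5.699e-5, rel=1e-3)

    def test_symmetric_null(self):
        assert mann_kendall_pvalue(PairCounts(5, 5, 0, 0, 0, 10), 5) == 1.0

    def test_small_n_closed_form(self):
        # n=3, S=3: Var = 3*2*11/18 = 11/3
        counts = PairCounts(3, 0, 0, 0, 0, 3)
        z = 3 / math.sqrt(11 / 3)
        assert mann_kendall_pvalue(counts, 3) == pytest.approx(2 * norm.sf(z), rel=1e-12)

    def test_all_tied_variance_undefined(self):
        counts = PairCounts(0, 0, 3, 3, 3, 3, x_tie_sizes=(3,), y_tie_sizes=(3,))
        with pytest.raises(UndefinedCorrelationError):
            mann_kendall_pvalue(counts, 3)


class TestFastPath:
    def test_examples(self):
        assert ici_kt_fast([1, 2, NA], [NA, 3, 2]).tau == pytest.approx(1 / 3, abs=1e-15)
        out = ici_kt_fast([1, 2, 3, 4], [1, 2, 3, 4])
        assert out.tau == pytest.approx(1.0, abs=1e-15) and out.p_value < 1
        assert ici_kt_fast([1, 2, NA, NA], [2, 3, NA, NA], "global").tau == pytest.approx(1.0)

    def test_outcome_carries_census_and_completeness(self):
        out = ici_kt_fast([1, NA, 3, 4], [1, 2, NA, 4], "global")
        assert out.completeness == 0.5
        assert out.counts.n_tot == 6
        assert out.n_effective == 4

    def test_local_n_effective_shrinks(self):
        out = ici_kt_fast([1, 2, NA, NA], [2, 3, NA, NA], "local")
        assert out.n_effective == 2
        # completeness is still reported on the full vectors
        assert out.completeness == 0.5

    def test_degenerate_all_tied(self):
        with pytest.raises(UndefinedCorrelationError):
            ici_kt_fast([1, 1, 1], [1, 2, 3])

    @given(st.data())
    def test_oracle_equivalence(self, data):
        """Fast sentinel-substitution path equals the rule-based census exactly."""
        from conftest import random_missing_pair

        seed = data.draw(st.integers(0, 2**31 - 1))
        perspective = data.draw(st.sampled_from(["local", "global"]))
        rng = np.random.default_rng(seed)
        x, y = random_missing_pair(rng, ties=True)
        try:
            brute = count_pairs_bruteforce(x, y, perspective)
            t_brute = tau_b_from_counts(brute)
        except UndefinedCorrelationError:
            with pytest.raises(UndefinedCorrelationError):
                ici_kt_fast(x, y, perspective)
            return
        out = ici_kt_fast(x, y, perspective)
        assert out.counts == brute
        assert out.tau == pytest.approx(t_brute, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_bounds(self, seed):
        from conftest import random_missing_pair

        rng = np.random.default_rng(seed)
        x, y = random_missing_pair(rng, ties=True)
        try:
            a = ici_kt_fast(x, y, "global")
            b = ici_kt_fast(y, x, "global")
        except UndefinedCorrelationError:
            return
        assert a.tau == pytest.approx(b.tau, abs=1e-15)
        assert abs(a.tau) <= 1.0 + 1e-15
        assert 0.0 <= a.completeness <= 1.0
        assert 0.0 < a.tau_max <= 1.0 + 1e-12
        if a.counts.s_statistic >= 0:
            assert a.tau <= a.tau_max + 1e-12

    @given(st.integers(0, 2**31 - 1))
    def test_reduces_to_classical_tau_b_without_missing(self, seed):
        """With no missing values ICI-Kt is textbook tau-b (scipy cross-check)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        x = np.round(rng.normal(size=n), 1)
        y = np.round(x + rng.normal(size=n), 1)
        ref = kendalltau(x, y, method="asymptotic")
        try:
            out = ici_kt_fast(x, y)
        except UndefinedCorrelationError:
            assert np.isnan(ref.statistic)
            return
        assert out.tau == pytest.approx(ref.statistic, abs=1e-12)
        assert out.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_zero_replacement_identity(self, seed):
        """For all-positive data, ICI-Kt equals classical tau-b after 0-substitution."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        x = rng.lognormal(1, 0.5, n)
        y = rng.lognormal(1, 0.5, n)
        x[rng.random(n) < 0.3] = np.nan
        y[rng.random(n) < 0.3] = np.nan
        try:
            out = ici_kt_fast(x, y, "global")
        except UndefinedCorrelationError:
            return
        ref = kendalltau(np.nan_to_num(x), np.nan_to_num(y), method="asymptotic")
        assert out.tau == pytest.approx(ref.statistic, abs=1e-12)
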