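"""Unit tests for the anchor combinatorics."""

import math
from fractions import Fraction

import numpy as np

import pytest

from smsmap.anchor_stats import (
    AnchorCountTable,
    CompositionQuery,
    RunModelParams,
    anchor_count_table,
    anchors_first_compositions,
    composition_moments,
    compositions_closed,
    compositions_poly,
    enumerate_oracle,
    mean_run_length,
    normal_approx,
    num_configurations,
    run_length_sf,
    waiting_length,
)


class TestToyExample:
    """Read of length 7 with 2 errors, minimum anchor length 3."""

    def test_anchors_first_compositions(self):
        got = set(anchors_first_compositions(2, 1, 3, 7))
        assert got == {(4, 3, 1), (4, 2, 2), (4, 1, 3), (5, 2, 1), (5, 1, 2), (6, 1, 1)}

    def test_exactly_one_anchor_count(self):
        q = CompositionQuery(2, 1, 3, 7)
        assert compositions_poly(q) == 18
        assert compositions_closed(q).value == 18

    def test_exhaustive_histogram(self):
        assert enumerate_oracle(2, 3, 7) == {0: 3, 1: 18}

    def test_survival_and_probability(self):
        count, prob = num_configurations(2, 1, 3, 7)
        assert count == 18
        assert prob == Fraction(6, 7)

    def test_zero_anchors_required_is_unconstrained(self):
        count, prob = num_configurations(2, 0, 3, 7)
        assert count == math.comb(7, 2)
        assert prob == 1


class TestCompositionCounts:
    def test_total_over_N_is_binomial(self):
        # Sum over all N of c_{M,N,K}(L) counts every error placement once.
        for M, K, L in [(2, 3, 7), (4, 2, 11), (3, 5, 14)]:
            total = sum(
                compositions_poly(CompositionQuery(M, N, K, L)) for N in range(M + 2)
            )
            assert total == math.comb(L, M)

    @pytest.mark.parametrize("L", [6, 9, 12, 14])
    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    def test_poly_equals_closed_equals_enumeration(self, L, K):
        for M in range(0, min(L, 5) + 1):
            hist = enumerate_oracle(M, K, L)
            for N in range(M + 2):
                q = CompositionQuery(M, N, K, L)
                expected = hist.get(N, 0)
                assert compositions_poly(q) == expected
                assert compositions_closed(q).value == expected

    def test_k_zero_all_parts_are_anchors(self):
        q = CompositionQuery(3, 4, 0, 9)
        assert compositions_poly(q) == math.comb(9, 3)
        assert compositions_closed(q).value == math.comb(9, 3)
        assert compositions_poly(CompositionQuery(3, 2, 0, 9)) == 0

    def test_structurally_impossible_queries_are_zero(self):
        # two anchors of length > 3 cannot fit in 8 positions
        assert compositions_poly(CompositionQuery(2, 2, 3, 7)) == 0
        assert compositions_closed(CompositionQuery(2, 2, 3, 7)).value == 0


class TestClosedFormDiagnostics:
    def test_alternating_sum_worked_case(self):
        """The L=1000, M=75, N=1, K=15 sum: 61 nonzero terms whose
        magnitudes dwarf the result (401- vs 294-bit), demanding exact
        integers."""
        res = compositions_closed(CompositionQuery(75, 1, 15, 1000))
        assert res.n_nonzero == 61
        assert res.max_abs.bit_length() == 401
        assert res.min_abs.bit_length() == 93
        assert res.sum_abs.bit_length() == 294
        assert res.value == compositions_poly(CompositionQuery(75, 1, 15, 1000))

    def test_intermediate_poly_values_nonnegative(self):
        # the polynomial route must never produce a negative intermediate;
        # spot-check by verifying all table entries are nonnegative and sum
        tab = anchor_count_table(9, 5, 60)
        assert all(c >= 0 for c in tab.counts)
        assert sum(tab.counts) == tab.total


class TestMoments:
    def test_toy_moments_match_exhaustive_distribution(self):
        m = composition_moments(2, 3, 7)
        assert m.mu == Fraction(6, 7)
        assert m.sigma2 == Fraction(6, 49)

    def test_moments_match_exact_table(self):
        L, M, K = 60, 9, 5
        tab = anchor_count_table(M, K, L)
        total = tab.total
        mu = Fraction(sum(N * c for N, c in enumerate(tab.counts)), total)
        ex2 = Fraction(sum(N * N * c for N, c in enumerate(tab.counts)), total)
        m = composition_moments(M, K, L)
        assert m.mu == mu
        assert m.sigma2 == ex2 - mu * mu

    def test_k_zero_degenerate(self):
        m = composition_moments(4, 0, 10)
        assert m.mu == 5 and m.sigma2 == 0

    def test_mean_zero_when_anchors_cannot_fit(self):
        assert composition_moments(9, 5, 12).mu == 0


class TestNormalApprox:
    def test_survival_matches_exact_near_mean(self):
        # at the distribution's center the corrected normal survival should
        # track the exact suffix sum closely (computed oracle: 0.7883)
        L, M, K = 60, 9, 5
        N = round(float(composition_moments(M, K, L).mu))
        total = math.comb(L, M)
        _, surv = normal_approx(M, N, K, L)
        exact = anchor_count_table(M, K, L).survival(N) / total
        assert surv / total == pytest.approx(exact, abs=0.02)

    def test_survival_non_increasing(self):
        total = math.comb(60, 9)
        vals = [normal_approx(9, N, 5, 60)[1] / total for N in range(11)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_pmf_close_to_exact_midscale(self):
        # scaled-down check; the full-scale one lives in the acceptance suite
        L, M, K = 200, 30, 8
        tab = anchor_count_table(M, K, L)
        total = tab.total
        worst = max(
            abs(normal_approx(M, N, K, L)[0] - tab.counts[N]) / total
            for N in range(M + 2)
        )
        assert worst < 0.02


class TestRunModel:
    def test_waiting_length_closed_form(self):
        t, _ = waiting_length(RunModelParams(0.5, 1, 0.05))
        assert t == pytest.approx(math.log(0.05) / math.log(0.5), rel=1e-12)

    def test_waiting_length_monte_carlo(self, rng):
        """Simulate the word process: words have geometric length, and we
        count words until one reaches length >= K."""
        params = RunModelParams(0.15, 15, 0.05)
        t, bases = waiting_length(params)
        assert t == pytest.approx(32.77, abs=0.01)
        # MC: P(word >= K) = 0.85^15; t solves (1-p)^t = eps
        p = 0.85**15
        n = 200_000
        draws = rng.geometric(p, size=n)  # words until first anchor
        # t is the eps-quantile of the waiting distribution
        emp_t = float(np.quantile(draws, 1 - params.epsilon))
        assert emp_t == pytest.approx(t, rel=0.05)
        assert 150 < bases < 200

    def test_epsilon_to_one_limit(self):
        t, _ = waiting_length(RunModelParams(0.15, 15, 0.999999))
        assert t < 1e-4

    def test_mean_run_length(self):
        assert round(mean_run_length(0.15), 2) == 5.67

    def test_run_length_sf_is_geometric(self):
        assert run_length_sf(15, 0.85) == pytest.approx(0.85**15)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            RunModelParams(0.0, 15, 0.05)
        with pytest.raises(ValueError):
            RunModelParams(1.0, 15, 0.05)
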