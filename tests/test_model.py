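"""Forward model and closed-form inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attnalloc.model import (
    DEGENERATE,
    SPECIOUS_G,
    SPECIOUS_P,
    VALID,
    VARIANT_CONSISTENT,
    VARIANT_LINEAR,
    VARIANT_PAPER,
    VARIANT_ROW,
    AccuracyProfile,
    AttentionSolution,
    ConditionDesign,
    RatePair,
    chance_guess_rate,
    classify_solution,
    expected_overall_correct,
    expected_row_correct_frequency,
    forward_conditional_rates,
    invert_equal_accuracy,
    invert_row_accuracy,
)
from conftest import grid_invert

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestChanceGuessRate:
    @pytest.mark.parametrize(
        "n, expected", [(7, 1 / 7), (1, 1.0), (4, 0.25)]
    )
    def test_uniform_guessing(self, n, expected):
        assert chance_guess_rate(n) == pytest.approx(expected, abs=1e-15)

    def test_seven_options_prints_as_0143(self):
        assert round(chance_guess_rate(7), 3) == 0.143

    def test_zero_options_rejected(self):
        with pytest.raises(ValueError):
            chance_guess_rate(0)


class TestForwardModel:
    @pytest.mark.parametrize(
        "p, g, a, expected",
        [
            (0.75, 1 / 7, None, (0.785714285714, 0.357142857142)),
            (1.0, 0.0, None, (1.0, 0.0)),
            (0.75, 1 / 7, 0.9, (0.707142857142, 0.321428571428)),
        ],
    )
    def test_conditional_rates(self, p, g, a, expected):
        rates = forward_conditional_rates(p, g, a)
        assert rates.pct == pytest.approx(expected[0], abs=1e-9)
        assert rates.pcb == pytest.approx(expected[1], abs=1e-9)

    def test_row_specific_accuracy_scales_each_rate(self):
        acc = AccuracyProfile(0.96, 0.8, 0.9)
        rates = forward_conditional_rates(0.75, 1 / 7, acc)
        assert rates.pct == pytest.approx(0.96 * 0.785714285714, abs=1e-9)
        assert rates.pcb == pytest.approx(0.8 * 0.357142857142, abs=1e-9)

    @pytest.mark.parametrize(
        "pt, p, g, expected",
        [
            # Exhaustive expectation over (match row x attended row) outcomes.
            (0.75, 0.75, 0.143, 0.678625),
            (0.5, 0.5, 0.0, 0.5),
            (0.3, 0.7, 1.0, 1.0),
        ],
    )
    def test_overall_correct(self, pt, p, g, expected):
        design = ConditionDesign.from_top(pt)
        assert expected_overall_correct(design, p, g) == pytest.approx(
            expected, abs=1e-12
        )

    def test_overall_correct_brute_force_enumeration(self, rng):
        # Oracle: sum over the four (match row, attended row) outcomes.
        for _ in range(50):
            pt, p, g = rng.uniform(size=3)
            design = ConditionDesign(pt, 1 - pt)
            expect = (
                pt * p * 1.0
                + pt * (1 - p) * g
                + (1 - pt) * (1 - p) * 1.0
                + (1 - pt) * p * g
            )
            assert expected_overall_correct(design, p, g) == pytest.approx(
                expect, abs=1e-12
            )

    def test_overall_correct_maximized_at_extreme_allocation(self):
        grid = np.linspace(0.0, 1.0, 101)
        for pt, g in [(0.75, 0.14), (0.9, 0.5), (0.25, 0.0), (0.1, 0.9)]:
            design = ConditionDesign.from_top(pt)
            vals = [expected_overall_correct(design, p, g) for p in grid]
            argmax = grid[int(np.argmax(vals))]
            assert argmax == (1.0 if pt > 0.5 else 0.0)

    @pytest.mark.parametrize(
        "pt, p, g, expected, tol",
        [
            (0.75, 0.75, 0.143, 0.589, 5e-4),  # hand-worked benchmark, 3 d.p.
            (1.0, 1.0, 0.0, 1.0, 1e-12),
            (0.5, 0.0, 1 / 7, 0.0714285714, 1e-9),
        ],
    )
    def test_row_correct_frequency(self, pt, p, g, expected, tol):
        design = ConditionDesign.from_top(pt)
        assert expected_row_correct_frequency(design, p, g) == pytest.approx(
            expected, abs=tol
        )

    def test_design_requires_complementary_probabilities(self):
        with pytest.raises(ValueError):
            ConditionDesign(0.75, 0.35)


class TestEqualAccuracyInversion:
    @pytest.mark.parametrize(
        "pct, pcb, a, variant, p_exp, g_exp",
        [
            (0.785714, 0.357143, 1.0, VARIANT_PAPER, 0.750, 0.142857),
            (1.0, 0.0, 1.0, VARIANT_PAPER, 1.0, 0.0),
            (0.5, 0.5, 1.0, VARIANT_PAPER, 0.5, 0.0),
            # Multiplicative model at p=0.75, g=1/7, A=0.9: the printed
            # equations return g-hat = A*g, the consistent form returns g.
            (0.707143, 0.321429, 0.9, VARIANT_PAPER, 0.750, 0.128571),
            (0.707143, 0.321429, 0.9, VARIANT_CONSISTENT, 0.750, 0.142857),
        ],
    )
    def test_examples(self, pct, pcb, a, variant, p_exp, g_exp):
        sol = invert_equal_accuracy(RatePair(pct, pcb), a, variant)
        assert sol.validity == VALID
        assert sol.p == pytest.approx(p_exp, abs=5e-6)
        assert sol.g == pytest.approx(g_exp, abs=5e-6)

    def test_perfect_accuracy_records_linear_variant(self):
        sol = invert_equal_accuracy(RatePair(0.8, 0.4), 1.0, VARIANT_CONSISTENT)
        assert sol.variant == VARIANT_LINEAR
        sol = invert_equal_accuracy(RatePair(0.8, 0.4), 0.95, VARIANT_PAPER)
        assert sol.variant == VARIANT_PAPER

    def test_degenerate_denominator(self):
        sol = invert_equal_accuracy(RatePair(0.9, 0.9), 0.9)
        assert sol.validity == DEGENERATE
        assert sol.p is None

    def test_zero_accuracy_rejected(self):
        with pytest.raises(ValueError):
            invert_equal_accuracy(RatePair(0.5, 0.5), 0.0)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(p=probs, g=st.floats(0.0, 0.9))
    def test_round_trip_error_free(self, p, g):
        rates = forward_conditional_rates(p, g)
        sol = invert_equal_accuracy(rates, 1.0)
        assert sol.validity == VALID
        assert sol.p == pytest.approx(p, abs=1e-12)
        assert sol.g == pytest.approx(g, abs=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(p=probs, g=st.floats(0.0, 0.9), a=st.floats(0.5, 1.0))
    def test_round_trip_consistent_variant_any_accuracy(self, p, g, a):
        rates = forward_conditional_rates(p, g, a)
        sol = invert_equal_accuracy(rates, a, VARIANT_CONSISTENT)
        assert sol.p == pytest.approx(p, abs=1e-9)
        assert sol.g == pytest.approx(g, abs=1e-9)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(p=probs, g=st.floats(0.0, 0.9), a=st.floats(0.5, 1.0))
    def test_paper_variant_g_scales_with_accuracy(self, p, g, a):
        rates = forward_conditional_rates(p, g, a)
        sol = invert_equal_accuracy(rates, a, VARIANT_PAPER)
        assert sol.g == pytest.approx(a * g, abs=1e-9)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(p=probs, g=probs)
    def test_conservation_sum_of_rates(self, p, g):
        rates = forward_conditional_rates(p, g)
        assert rates.pct + rates.pcb == pytest.approx(1.0 + g, abs=1e-12)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(p=probs, g=probs, a=st.floats(0.1, 1.0))
    def test_conservation_with_accuracy(self, p, g, a):
        rates = forward_conditional_rates(p, g, a)
        assert rates.pct + rates.pcb == pytest.approx(a * (1.0 + g), abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        p1=st.floats(0.0, 0.999),
        dp=st.floats(1e-6, 0.5),
        g=st.floats(0.0, 0.99),
    )
    def test_monotonic_in_allocation(self, p1, dp, g):
        p2 = min(p1 + dp, 1.0)
        r1 = forward_conditional_rates(p1, g)
        r2 = forward_conditional_rates(p2, g)
        if p2 > p1:
            assert r2.pct > r1.pct
            assert r2.pcb < r1.pcb


class TestRowAccuracyInversion:
    @pytest.mark.parametrize(
        "pct, pcb, a_top, a_bottom, p_exp, g_exp",
        [
            (0.785714, 0.357143, 1.0, 1.0, 0.750, 0.142857),
            (0.9, 0.0, 0.9, 1.0, 1.0, 0.0),
            (0.754286, 0.285714, 0.96, 0.8, 0.750, 0.142857),
        ],
    )
    @pytest.mark.parametrize("method", ["closed_form", "numeric"])
    def test_examples_both_paths(self, pct, pcb, a_top, a_bottom, p_exp, g_exp, method):
        acc = AccuracyProfile(a_top, a_bottom, (a_top + a_bottom) / 2)
        sol = invert_row_accuracy(RatePair(pct, pcb), acc, method=method)
        assert sol.validity == VALID
        assert sol.variant == VARIANT_ROW
        assert sol.p == pytest.approx(p_exp, abs=5e-6)
        assert sol.g == pytest.approx(g_exp, abs=5e-6)

    def test_equal_accuracies_reduce_to_consistent_variant(self, rng):
        for _ in range(25):
            p, g = rng.uniform(0.05, 0.95, size=2)
            a = rng.uniform(0.6, 1.0)
            rates = forward_conditional_rates(p, g, a)
            row = invert_row_accuracy(rates, AccuracyProfile.uniform(a))
            eq = invert_equal_accuracy(rates, a, VARIANT_CONSISTENT)
            assert row.p == pytest.approx(eq.p, abs=1e-9)
            assert row.g == pytest.approx(eq.g, abs=1e-9)

    def test_agrees_with_grid_search_oracle(self, rng):
        for _ in range(10):
            p, g = rng.uniform(0.1, 0.9, size=2)
            a_top, a_bottom = rng.uniform(0.7, 1.0, size=2)
            rates = forward_conditional_rates(
                p, g, AccuracyProfile(a_top, a_bottom, 0.9)
            )
            sol = invert_row_accuracy(rates, AccuracyProfile(a_top, a_bottom, 0.9))
            p_grid, g_grid = grid_invert(rates.pct, rates.pcb, a_top, a_bottom)
            assert sol.p == pytest.approx(p_grid, abs=1e-6)
            assert sol.g == pytest.approx(g_grid, abs=1e-6)

    def test_no_unit_square_solution_is_flagged_not_raised(self):
        sol = invert_row_accuracy(
            RatePair(1.0, 0.05), AccuracyProfile.uniform(0.9), method="numeric"
        )
        assert sol.validity in (SPECIOUS_P, SPECIOUS_G)

    def test_zero_accuracy_rejected(self):
        with pytest.raises(ValueError):
            invert_row_accuracy(RatePair(0.5, 0.5), AccuracyProfile(0.0, 1.0, 0.5))


class TestClassification:
    @pytest.mark.parametrize(
        "p, g, expected",
        [
            (1.2, 0.1, SPECIOUS_P),
            (0.6, -0.05, SPECIOUS_G),
            (0.0, 0.0, VALID),
            (1.0, 1.0, VALID),
            (None, 0.2, DEGENERATE),
        ],
    )
    def test_labels(self, p, g, expected):
        sol = classify_solution(AttentionSolution(p, g, VARIANT_LINEAR, VALID))
        assert sol.validity == expected

    def test_boundary_round_off_not_flagged(self):
        sol = classify_solution(
            AttentionSolution(1.0 + 1e-12, -1e-12, VARIANT_LINEAR, VALID)
        )
        assert sol.validity == VALID
        assert sol.p == 1.0
        assert sol.g == 0.0
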