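"""Weighted differentials, control-adjusted responses, realized heritability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import ols_closed_form
from selexsim.selection import (
    Direction,
    LineMeans,
    ResponseSeries,
    cumulative_differential,
    percent_change,
    realized_heritability,
    response_to_selection,
    weighted_selection_differential,
)


class TestWeightedSelectionDifferential:
    def test_direct_evaluation(self):
        rec = weighted_selection_differential(
            {"P1": 10.0, "P2": 14.0}, 11.0, {"P1": 5, "P2": 5}
        )
        assert rec.differential == pytest.approx(1.0)
        assert rec.contributions == {"P1": 0.5, "P2": 0.5}

    def test_centered_means_give_zero(self):
        rec = weighted_selection_differential(
            {"a": 3.0, "b": 3.0}, 3.0, {"a": 7, "b": 1}
        )
        assert rec.differential == 0.0

    @given(
        st.lists(st.floats(-100, 100), min_size=1, max_size=12),
        st.floats(-100, 100),
    )
    def test_uniform_counts_reduce_to_mean_deviation(self, means, mu):
        parent_means = {f"p{i}": m for i, m in enumerate(means)}
        rec = weighted_selection_differential(
            parent_means, mu, {k: 3 for k in parent_means}
        )
        assert rec.differential == pytest.approx(np.mean(means) - mu, abs=1e-9)

    @given(
        st.lists(
            st.tuples(st.floats(0, 20), st.integers(0, 50)),
            min_size=2,
            max_size=10,
        ).filter(lambda v: sum(c for _, c in v) > 0),
        st.floats(0, 20),
    )
    def test_matches_brute_force_summation(self, parents, mu):
        means = {f"p{i}": m for i, (m, _) in enumerate(parents)}
        counts = {f"p{i}": c for i, (_, c) in enumerate(parents)}
        rec = weighted_selection_differential(means, mu, counts)
        total = sum(counts.values())
        expected = sum(
            (means[k] - mu) * counts[k] / total for k in counts
        )
        assert rec.differential == pytest.approx(expected, abs=1e-9)
        assert sum(rec.contributions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_selection_differential({"a": 1.0}, 0.0, {"a": 0})

    def test_counted_parent_without_mean_named(self):
        with pytest.raises(ValueError, match="p9"):
            weighted_selection_differential({"a": 1.0}, 0.0, {"a": 1, "p9": 2})


class TestResponseToSelection:
    def test_identity_and_subtraction(self):
        lm = LineMeans(4, 1, mean_top=13.3, mean_bottom=7.0, mean_control=12.0)
        assert response_to_selection(lm, Direction.TOP_MINUS_CONTROL) == pytest.approx(1.3)
        lm2 = LineMeans(4, 1, mean_top=12.0, mean_bottom=7.0, mean_control=7.0)
        assert response_to_selection(lm2, Direction.BOTTOM_MINUS_CONTROL) == 0.0

    def test_missing_control_mean_rejected(self):
        lm = LineMeans(1, 1, mean_top=10.0, mean_bottom=9.0, mean_control=np.nan)
        with pytest.raises(ValueError, match="control"):
            response_to_selection(lm, Direction.TOP_MINUS_CONTROL)


class TestCumulativeDifferential:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ([1.0, -0.5, 0.8], [1.0, 1.5, 2.3]),
            ([0.0, 0.0], [0.0, 0.0]),
            ([-2.0], [2.0]),
        ],
    )
    def test_absolute_prefix_sums(self, s, expected):
        assert cumulative_differential(s) == pytest.approx(expected)

    def test_unsorted_generations_rejected(self):
        recs = [
            weighted_selection_differential({"a": 1.0}, 0.0, {"a": 1}, generation=g)
            for g in (2, 1)
        ]
        with pytest.raises(ValueError, match="sorted"):
            cumulative_differential(recs)

    def test_generation_gap_rejected(self):
        recs = [
            weighted_selection_differential({"a": 1.0}, 0.0, {"a": 1}, generation=g)
            for g in (0, 2)
        ]
        with pytest.raises(ValueError, match="gaps"):
            cumulative_differential(recs)


class TestRealizedHeritability:
    def test_collinear_points_recovered_exactly(self):
        series = ResponseSeries((1.0, 2.0, 3.0), (0.5, 1.0, 1.5),
                                Direction.TOP_MINUS_CONTROL)
        est = realized_heritability(series)
        assert est.slope == pytest.approx(0.5, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_three_point_closed_form(self):
        x, y = (1.0, 2.0, 4.0), (0.30, 0.45, 1.05)
        series = ResponseSeries(x, y, Direction.TOP_MINUS_CONTROL)
        est = realized_heritability(series)
        slope, intercept, se = ols_closed_form(x, y)
        assert est.slope == pytest.approx(slope, abs=1e-10)
        assert est.intercept == pytest.approx(intercept, abs=1e-10)
        assert est.slope_se == pytest.approx(se, abs=1e-10)

    def test_flat_series_zero_slope(self):
        series = ResponseSeries((1.0, 2.0, 3.0), (0.7, 0.7, 0.7),
                                Direction.TOP_MINUS_CONTROL)
        assert realized_heritability(series).slope == pytest.approx(0.0, abs=1e-12)

    def test_bottom_direction_negated_by_default(self):
        series = ResponseSeries((1.0, 2.0), (-0.3, -0.6),
                                Direction.BOTTOM_MINUS_CONTROL)
        assert realized_heritability(series).slope == pytest.approx(0.3)
        assert realized_heritability(series, negate_bottom=False).slope == pytest.approx(-0.3)

    def test_through_origin_and_origin_point(self):
        x, y = (1.0, 2.0), (0.4, 1.0)
        series = ResponseSeries(x, y, Direction.TOP_MINUS_CONTROL)
        est = realized_heritability(series, through_origin=True)
        slope, _, _ = ols_closed_form(x, y, through_origin=True)
        assert est.slope == pytest.approx(slope, abs=1e-10)
        assert est.intercept == 0.0
        est2 = realized_heritability(series, include_origin_point=True)
        assert est2.n_points == 3

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 10), st.floats(-5, 5)),
            min_size=3, max_size=10,
            unique_by=lambda t: round(t[0], 6),
        )
    )
    def test_matches_ols_oracle_on_random_series(self, pts):
        pts = sorted(pts)
        x = tuple(np.cumsum([p[0] for p in pts]))
        y = tuple(p[1] for p in pts)
        series = ResponseSeries(x, y, Direction.TOP_MINUS_CONTROL)
        est = realized_heritability(series)
        slope, intercept, _ = ols_closed_form(x, y)
        assert est.slope == pytest.approx(slope, abs=1e-10)
        assert est.intercept == pytest.approx(intercept, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 points"):
            realized_heritability(
                ResponseSeries((1.0,), (0.5,), Direction.TOP_MINUS_CONTROL)
            )
        with pytest.raises(ValueError, match="zero variance"):
            realized_heritability(
                ResponseSeries((2.0, 2.0), (0.5, 0.6), Direction.TOP_MINUS_CONTROL)
            )


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref, val, printed",
        [(11.5, 13.3, 15.7), (11.5, 7.00, -39.1), (7.00, 13.3, 90.0)],
    )
    def test_printed_flower_size_changes(self, ref, val, printed):
        assert round(percent_change(ref, val), 1) == pytest.approx(printed, abs=0.05)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
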