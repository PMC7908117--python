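"""Base degree models: hand-derived values, oracle agreement, invariances."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_absolute, oracle_deng, oracle_relative
from conftest import random_panel
from greyrank import (
    ImageKind,
    InvalidEpsilonError,
    LengthError,
    Panel,
    Series,
    absolute_degree,
    absolute_degrees,
    deng_coefficients,
    deng_degree,
    integral_stat,
    relative_degree,
    relative_degrees,
    zero_start_image,
)


class TestDeng:
    def test_hand_derived_coefficients(self, simple_panel):
        """Mean images (0.5,1,1.5) vs (1.5,1,0.5): deltas (1,0,1), so the
        reversed comparator gets coefficients (1/3, 1, 1/3)."""
        res = deng_coefficients(simple_panel, epsilon=0.5)
        np.testing.assert_allclose(res.coefficients[0], [1 / 3, 1, 1 / 3], atol=1e-15)
        np.testing.assert_allclose(res.coefficients[1], [1, 1, 1], atol=1e-15)

    def test_hand_derived_degrees(self, simple_panel):
        degrees = deng_degree(simple_panel, epsilon=0.5).degrees
        assert degrees["down"] == pytest.approx(5 / 9, abs=1e-12)
        assert degrees["same"] == pytest.approx(1.0, abs=1e-15)

    def test_degree_is_mean_of_coefficient_row(self):
        rng = np.random.default_rng(7)
        panel = random_panel(rng, m=6, n=3)
        res = deng_coefficients(panel)
        for i, name in enumerate(res.names):
            assert res.degrees[name] == pytest.approx(
                res.coefficients[i].mean(), abs=1e-12
            )

    def test_proportional_comparator_scores_one(self):
        """Scaling leaves the mean image unchanged, so (2,4,6) vs (1,2,3)
        is a perfect match."""
        panel = Panel(Series("ref", [1, 2, 3]), (Series("c", [2, 4, 6]),))
        assert deng_degree(panel, 0.5).degrees["c"] == pytest.approx(1.0, abs=1e-15)

    def test_degenerate_panel_all_ones(self):
        panel = Panel(Series("ref", [1, 2, 3]), (Series("c", [1, 2, 3]),))
        res = deng_coefficients(panel)
        np.testing.assert_array_equal(res.coefficients, 1.0)
        assert res.degrees["c"] == 1.0

    @pytest.mark.parametrize("epsilon", [0.0, -0.1, 1.5])
    def test_epsilon_validation(self, simple_panel, epsilon):
        with pytest.raises(InvalidEpsilonError):
            deng_degree(simple_panel, epsilon)

    def test_scale_invariance_of_any_single_series(self):
        rng = np.random.default_rng(11)
        panel = random_panel(rng, m=5, n=3)
        base = deng_degree(panel).degrees
        scaled = Panel(
            panel.reference.with_values(panel.reference.values * 37.5),
            panel.comparators,
        )
        for name, v in deng_degree(scaled).degrees.items():
            assert v == pytest.approx(base[name], abs=1e-10)


class TestIntegralStat:
    @pytest.mark.parametrize(
        ("values", "expected"),
        [([0, 1, 2], 2.0), ([0, 0, 0], 0.0), ([0, 2, 4], 4.0)],
    )
    def test_direct_evaluation(self, values, expected):
        assert integral_stat(Series("s", values)).s_value == pytest.approx(expected)

    def test_m2_middle_sum_empty(self):
        assert integral_stat(Series("s", [0.0, 3.0])).s_value == pytest.approx(1.5)


class TestAbsolute:
    def test_hand_derived(self):
        """Zero-start images (0,1,2) and (0,2,4): s0=2, si=4, degree 7/9."""
        assert absolute_degree(
            Series("r", [1, 2, 3]), Series("x", [1, 3, 5])
        ) == pytest.approx(7 / 9, abs=1e-15)

    def test_shift_gives_one(self):
        assert absolute_degree(
            Series("r", [1, 2, 3]), Series("x", [11, 12, 13])
        ) == pytest.approx(1.0, abs=1e-15)

    def test_identical_gives_one(self):
        s = Series("r", [2.5, 0.5, 9.0])
        assert absolute_degree(s, Series("x", s.values)) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(LengthError):
            absolute_degree(Series("r", [1, 2, 3]), Series("x", [1, 2]))

    def test_m2_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            absolute_degree(Series("r", [1.0, 2.0]), Series("x", [3.0, 1.0]))


class TestRelative:
    def test_proportional_gives_one(self):
        assert relative_degree(
            Series("r", [2, 4, 6]), Series("x", [3, 6, 9])
        ) == pytest.approx(1.0, abs=1e-15)

    def test_hand_derived(self):
        """Initial images (1,2,3) and (1,1,1): s0'=2, si'=0, degree 3/5."""
        assert relative_degree(
            Series("r", [1, 2, 3]), Series("x", [2, 2, 2])
        ) == pytest.approx(0.6, abs=1e-15)

    def test_identical_gives_one(self):
        s = Series("r", [4.0, 1.0, 2.0])
        assert relative_degree(s, Series("x", s.values)) == 1.0

    def test_mean_anchored_variant(self):
        """The documented alternative normalization divides by the mean; for
        proportional series it still yields a perfect degree."""
        d = relative_degree(
            Series("r", [2, 4, 6]), Series("x", [1, 2, 3]), image=ImageKind.MEAN
        )
        assert d == pytest.approx(1.0, abs=1e-12)


def test_oracle_agreement_small_panels():
    """Production (vectorized) degrees match the naive loop transcriptions."""
    rng = np.random.default_rng(2024)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(200):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(1, 5))
            panel = random_panel(rng, m=m, n=n)
            ref = panel.reference.values.tolist()
            comps = [c.values.tolist() for c in panel.comparators]
            expected = oracle_deng(ref, comps, 0.5)
            got = deng_degree(panel, 0.5).degrees
            for j, c in enumerate(panel.comparators):
                assert got[c.name] == pytest.approx(expected[j], abs=1e-12)
                assert absolute_degree(panel.reference, c) == pytest.approx(
                    oracle_absolute(ref, comps[j]), abs=1e-12
                )
                assert relative_degree(panel.reference, c) == pytest.approx(
                    oracle_relative(ref, comps[j]), abs=1e-12
                )


positive_values = st.lists(
    st.floats(min_value=0.1, max_value=100.0), min_size=3, max_size=8
)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(v0=positive_values, v1=positive_values, shift=st.floats(-50, 50))
def test_absolute_shift_invariance(v0, v1, shift):
    n = min(len(v0), len(v1))
    x0, xi = Series("r", v0[:n]), Series("x", v1[:n])
    base = absolute_degree(x0, xi)
    assert absolute_degree(
        x0.with_values(x0.values + shift), xi
    ) == pytest.approx(base, abs=1e-9)
    assert absolute_degree(
        x0, xi.with_values(xi.values + shift)
    ) == pytest.approx(base, abs=1e-9)


@settings(derandomize=True, max_examples=80, deadline=None)
@given(v0=positive_values, v1=positive_values, c=st.floats(0.01, 100.0))
def test_relative_scale_invariance(v0, v1, c):
    n = min(len(v0), len(v1))
    x0, xi = Series("r", v0[:n]), Series("x", v1[:n])
    base = relative_degree(x0, xi)
    assert relative_degree(
        x0.with_values(x0.values * c), xi
    ) == pytest.approx(base, abs=1e-9)
    assert relative_degree(
        x0, xi.with_values(xi.values * c)
    ) == pytest.approx(base, abs=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), eps=st.floats(0.01, 1.0))
def test_degrees_in_unit_interval(seed, eps):
    rng = np.random.default_rng(seed)
    panel = random_panel(rng, m=int(rng.integers(3, 7)), n=int(rng.integers(1, 5)))
    res = deng_coefficients(panel, eps)
    assert np.all(res.coefficients > 0) and np.all(res.coefficients <= 1)
    for result in (
        deng_degree(panel, eps),
        absolute_degrees(panel),
        relative_degrees(panel),
    ):
        for v in result.degrees.values():
            assert 0 < v <= 1


def test_reference_included_as_comparator_scores_exactly_one():
    rng = np.random.default_rng(3)
    ref = Series("ref", rng.uniform(1, 10, 6))
    panel = Panel(
        ref,
        (Series("copy", ref.values.copy()), Series("other", rng.uniform(1, 10, 6))),
    )
    assert deng_degree(panel).degrees["copy"] == 1.0
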