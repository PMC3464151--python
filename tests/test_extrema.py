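import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_dataset
from orderspc import (InsufficientDataError, OracleSizeError, ParityCase,
                      brute_force_extrema, compute_extrema, deltas,
                      extremal_orderings, max_coefficients, mr_bar,
                      mr_bar_range, s_max, s_min)


class TestDeltas:
    @pytest.mark.parametrize("values,expected", [
        ([0, 1, 3], (1.0, 2.0)),
        ([5, 5, 5], (0.0, 0.0)),
        ([75, 16.7], (58.3,)),   # Table-1-style min/max pair
        ([3, 1, 0], (1.0, 2.0)),  # sorting is applied first
    ])
    def test_gaps_of_sorted_values(self, values, expected):
        dv = deltas(values)
        assert dv.deltas == pytest.approx(expected)
        assert sorted(values) == list(dv.sorted_values)
        assert sum(dv.deltas) == pytest.approx(dv.sorted_values[-1] - dv.sorted_values[0])

    def test_requires_two_points(self):
        with pytest.raises(InsufficientDataError):
            deltas([1.0])


class TestClosedForms:
    def test_s_min_is_range_over_orderings(self):
        s, mr_min = s_min([0, 1, 3])
        assert (s, mr_min) == (3.0, 1.5)
        assert s_min([7, 7, 7])[0] == 0.0
        # 23 points spanning [16.7, 75]: mR_min = 58.3/22
        values = np.linspace(16.7, 75, 23)
        assert s_min(values)[1] == pytest.approx(58.3 / 22)

    @pytest.mark.parametrize("values,expected_s,case", [
        ([0, 1, 3], 5.0, ParityCase.ODD_CASE_I_A),
        ([0, 3, 4], 7.0, ParityCase.ODD_CASE_I_B),
        ([0, 1, 2, 4], 9.0, ParityCase.EVEN_CASE_II),
        ([1, 2], 1.0, ParityCase.DEGENERATE_N2),
    ])
    def test_s_max_branches(self, values, expected_s, case):
        s, mr_max, fired = s_max(values)
        assert s == expected_s
        assert mr_max == expected_s / (len(values) - 1)
        assert fired is case

    def test_equal_central_deltas_make_both_odd_branches_agree(self):
        # delta = (2, 2): coefficient vectors (1,2) and (2,1) give the same S
        values = [0.0, 2.0, 4.0]
        s, _, _ = s_max(values)
        dv = deltas(values)
        assert s == np.dot((1, 2), dv.deltas) == np.dot((2, 1), dv.deltas)

    def test_coefficients_palindromic_structure(self):
        even = max_coefficients(deltas(list(range(8))))
        assert even == (2, 4, 6, 7, 6, 4, 2)
        assert even == even[::-1]
        odd = max_coefficients(deltas([0, 1, 2, 3, 5, 6, 7]))  # upper central gap larger
        assert odd == (2, 4, 5, 6, 4, 2)
        outer = odd[:2] + odd[4:]
        assert outer == outer[::-1]

    def test_scale_shift_equivariance(self, rng):
        values = rng.uniform(0, 100, 10)
        base_min, base_max = s_min(values)[0], s_max(values)[0]
        for a, b in [(2.5, -7.0), (-3.0, 40.0)]:
            scaled = a * values + b
            assert s_min(scaled)[0] == pytest.approx(abs(a) * base_min)
            assert s_max(scaled)[0] == pytest.approx(abs(a) * base_max)


class TestOracleEquivalence:
    def test_closed_forms_match_brute_force_on_mixed_grid(self, rng):
        for n in range(3, 9):
            for trial in range(30):
                kind = ("int", "progression", "float")[trial % 3]
                values = random_dataset(rng, n, kind)
                bf = brute_force_extrema(values)
                assert s_min(values)[0] == pytest.approx(bf.s_min, rel=1e-12, abs=1e-12)
                assert s_max(values)[0] == pytest.approx(bf.s_max, rel=1e-12, abs=1e-12)

    def test_oracle_guard_at_ten_points(self):
        with pytest.raises(OracleSizeError):
            brute_force_extrema(list(range(10)))

    def test_oracle_halves_the_permutations(self):
        # {0,1,3}: the 3 reversal-distinct orderings give mR values 1.5, 2, 2.5
        res = brute_force_extrema([0, 1, 3])
        assert (res.mr_bar_min, res.mr_bar_max) == (1.5, 2.5)


class TestExtremalOrderings:
    def test_sorted_order_attains_the_minimum(self):
        min_ord, _ = extremal_orderings([3, 1, 4, 2])
        assert min_ord == (1.0, 2.0, 3.0, 4.0)
        assert mr_bar(min_ord) == 1.0

    def test_max_ordering_attains_brute_force_maximum(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            values = random_dataset(rng, n, ("float", "int")[n % 2])
            _, max_ord = extremal_orderings(values)
            assert sorted(max_ord) == sorted(float(v) for v in values)
            bf = brute_force_extrema(values)
            assert mr_bar(max_ord) == pytest.approx(bf.mr_bar_max, rel=1e-12, abs=1e-12)

    def test_verified_construction_scales_past_the_oracle(self, rng):
        # n > 9 has no exhaustive fallback: compute_extrema raising nothing
        # means the construction met the closed form at 1e-12.
        for n in (11, 23, 60):
            res = compute_extrema(rng.uniform(0, 100, n))
            assert mr_bar(res.max_ordering) == pytest.approx(res.mr_bar_max, rel=1e-12)
            assert mr_bar(res.min_ordering) == pytest.approx(res.mr_bar_min, rel=1e-12)


class TestMrBarRange:
    def test_hand_identity_example(self):
        # {0,1,2,4}: S_max - S_min = 9 - 4 = 5 = (2-1)*1 + (3-1)*1 + (2-1)*2
        assert mr_bar_range([0, 1, 2, 4]) == pytest.approx((9 - 4) / 3)

    def test_constant_data_has_zero_range(self):
        assert mr_bar_range([5, 5, 5, 5]) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=12))
    def test_reduction_identity_holds_exactly_on_integers(self, values):
        smx = s_max(values)[0]
        smn = s_min(values)[0]
        dv = deltas(values)
        reduced = float(np.dot(np.asarray(max_coefficients(dv)) - 1, dv.deltas))
        assert smx - smn == reduced
        assert mr_bar_range(values) == (smx - smn) / (len(values) - 1)


class TestSandwich:
    def test_every_ordering_lies_between_the_extrema(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 15))
            values = rng.uniform(0, 100, n)
            res = compute_extrema(values)
            shuffles = rng.permuted(np.tile(values, (200, 1)), axis=1)
            mr = np.abs(np.diff(shuffles, axis=1)).mean(axis=1)
            assert mr.min() >= res.mr_bar_min - 1e-9
            assert mr.max() <= res.mr_bar_max + 1e-9
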