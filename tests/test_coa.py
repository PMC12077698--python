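"""Crayfish optimizer and Pareto machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmdecg.coa import (
    COAConfig,
    ParetoFront,
    ackley,
    coa_minimize,
    crowding_distance,
    dominates,
    fast_non_dominated_sort,
    hypervolume_2d,
    mocoa,
    special_crowding_distance,
)


class TestAckley:
    def test_global_minimum(self):
        assert ackley(np.zeros(2)) == pytest.approx(0.0, abs=1e-12)
        assert ackley(np.zeros(7)) == pytest.approx(0.0, abs=1e-12)

    def test_direct_substitution_at_ones(self):
        # oracle: independent arithmetic evaluation of the defining expression
        x = np.array([1.0, 1.0])
        expected = (
            -20 * math.exp(-0.2 * math.sqrt(1.0))
            - math.exp(math.cos(2 * math.pi))
            + 20
            + math.e
        )
        assert ackley(x) == pytest.approx(expected, rel=1e-12)

    @given(st.lists(st.floats(-30, 30), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_even_function(self, xs):
        x = np.asarray(xs)
        assert ackley(x) == pytest.approx(ackley(-x), rel=1e-9, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ackley([])


class TestDominance:
    @pytest.mark.parametrize(
        "u, v, expected",
        [((1, 2), (2, 3), True), ((1, 2), (1, 2), False), ((1, 3), (2, 2), False)],
    )
    def test_basic_cases(self, u, v, expected):
        assert dominates(u, v) is expected
        if not expected and u != v:
            assert dominates(v, u) is False  # incomparable pairs

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dominates((1, 2), (1, 2, 3))


class TestNonDominatedSort:
    def test_single_and_identical_points(self):
        ranks, fronts = fast_non_dominated_sort([[1.0, 2.0]])
        assert list(ranks) == [1]
        ranks, _ = fast_non_dominated_sort([[1.0, 2.0]] * 4)
        assert list(ranks) == [1, 1, 1, 1]

    def test_matches_exhaustive_oracle(self, rng):
        """Peeling oracle: repeatedly remove the non-dominated subset."""
        F = rng.uniform(0, 1, (50, 2))
        ranks, _ = fast_non_dominated_sort(F)

        remaining = list(range(50))
        expected = np.zeros(50, dtype=int)
        r = 1
        while remaining:
            nd = [
                i
                for i in remaining
                for _ in [None]
                if not any(dominates(F[j], F[i]) for j in remaining if j != i)
            ]
            for i in nd:
                expected[i] = r
            remaining = [i for i in remaining if i not in nd]
            r += 1
        assert np.array_equal(ranks, expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fast_non_dominated_sort([])


class TestCrowding:
    def test_hand_case_single_objective(self):
        d = crowding_distance([[0.0], [0.5], [1.0]])
        assert d[1] == pytest.approx(1.0)
        assert math.isinf(d[0]) and math.isinf(d[2])

    def test_identical_points_interior_zero(self):
        d = crowding_distance([[1.0, 1.0]] * 3)
        assert d[1] == 0.0  # zero numerator, zero-span dims contribute nothing

    def test_special_crowding_branches(self):
        assert special_crowding_distance(0.9, 0.2, 0.5, 0.5) == 0.9  # max branch
        assert special_crowding_distance(0.1, 0.2, 0.5, 0.5) == 0.1  # min branch
        assert special_crowding_distance(0.3, 0.3, 0.5, 0.5) == 0.3  # equal either way
        assert special_crowding_distance(0.3, 0.3, 0.2, 0.5) == 0.3


class TestCOA:
    def test_temperature_and_intake_model(self):
        cfg = COAConfig(N=5, T=2, lb=(-1.0,), ub=(1.0,), seed=0)
        rng = np.random.default_rng(0)
        temps = rng.uniform(0, 1, 10000) * 15 + 20
        assert temps.min() >= 20.0 and temps.max() <= 35.0
        p = lambda t: cfg.C1 / (math.sqrt(2 * math.pi) * cfg.sigma) * math.exp(
            -((t - cfg.mu) ** 2) / (2 * cfg.sigma**2)
        )
        assert p(25.0) > p(24.0) and p(25.0) > p(26.0)  # maximal at mu

    def test_converges_on_ackley_short_run(self):
        cfg = COAConfig(N=30, T=150, lb=(-32.0, -32.0), ub=(32.0, 32.0), seed=3)
        best, history = coa_minimize(ackley, cfg)
        assert best.fitness[0] < 0.5
        assert np.all(np.diff(history) <= 0)  # monotone best-so-far

    def test_positions_stay_in_bounds(self):
        hits = []

        def tracked(x):
            hits.append(x.copy())
            return ackley(x)

        cfg = COAConfig(N=10, T=20, lb=(-2.0, -1.0), ub=(2.0, 3.0), seed=1)
        coa_minimize(tracked, cfg)
        H = np.stack(hits)
        assert np.all(H[:, 0] >= -2.0) and np.all(H[:, 0] <= 2.0)
        assert np.all(H[:, 1] >= -1.0) and np.all(H[:, 1] <= 3.0)

    def test_seed_determinism(self):
        cfg = COAConfig(N=15, T=30, lb=(-5.0, -5.0), ub=(5.0, 5.0), seed=9)
        b1, h1 = coa_minimize(ackley, cfg)
        b2, h2 = coa_minimize(ackley, cfg)
        assert np.array_equal(b1.position, b2.position)
        assert np.array_equal(h1, h2)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            COAConfig(N=1, T=10, lb=(0.0,), ub=(1.0,))
        with pytest.raises(ValueError):
            COAConfig(N=5, T=10, lb=(1.0,), ub=(0.0,))


SCHAFFER = (lambda x: float(x[0] ** 2), lambda x: float((x[0] - 2.0) ** 2))


class TestMOCOA:
    def test_front_mutually_non_dominated_and_on_pareto_set(self):
        cfg = COAConfig(N=40, T=80, lb=(-5.0,), ub=(5.0,), seed=2)
        front, _ = mocoa(list(SCHAFFER), cfg)
        xs = front.positions().ravel()
        assert np.mean((xs >= -0.05) & (xs <= 2.05)) >= 0.95
        F = front.fitnesses()
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not dominates(F[i], F[j])

    def test_single_objective_rejected(self):
        with pytest.raises(ValueError):
            mocoa([SCHAFFER[0]], COAConfig(N=10, T=5, lb=(-1.0,), ub=(1.0,)))

    def test_seed_determinism(self):
        cfg = COAConfig(N=20, T=20, lb=(-5.0,), ub=(5.0,), seed=4)
        f1, _ = mocoa(list(SCHAFFER), cfg)
        f2, _ = mocoa(list(SCHAFFER), cfg)
        assert np.array_equal(f1.positions(), f2.positions())

    def test_pareto_front_container_validates(self):
        from vmdecg.coa import Individual

        good = [
            Individual(position=np.array([0.0]), fitness=np.array([0.0, 4.0])),
            Individual(position=np.array([2.0]), fitness=np.array([4.0, 0.0])),
        ]
        ParetoFront(members=good)
        bad = good + [Individual(position=np.array([3.0]), fitness=np.array([5.0, 1.0]))]
        with pytest.raises(ValueError):
            ParetoFront(members=bad)


class TestHypervolume:
    def test_rectangle_case(self):
        assert hypervolume_2d([[0.0, 0.0]], (2.0, 3.0)) == pytest.approx(6.0)

    def test_two_point_staircase(self):
        # hand-computed union of two rectangles
        hv = hypervolume_2d([[0.0, 2.0], [1.0, 0.0]], (3.0, 3.0))
        assert hv == pytest.approx(3.0 * 1.0 + 2.0 * 2.0)
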