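"""Tree-structured Parzen estimator search."""

import math

import numpy as np
import pytest

from vmdecg.tpe import (
    Dimension,
    SearchSpace,
    TrialRecord,
    default_hyperparam_space,
    history_from_json,
    history_to_json,
    parzen_density,
    tpe_acquisition,
    tpe_optimize,
    tpe_split,
)


def _history(losses):
    return [TrialRecord(config={"x": float(i)}, loss=l, trial_id=i) for i, l in enumerate(losses)]


class TestSplit:
    def test_good_set_size(self):
        good, bad, y_star = tpe_split(_history(np.linspace(0, 1, 10)), gamma=0.3)
        assert len(good) == 3 and len(bad) == 7

    def test_ties_broken_by_trial_order(self):
        good, _, _ = tpe_split(_history([0.5] * 10), gamma=0.3)
        assert [tr.trial_id for tr in good] == [0, 1, 2]

    def test_floor_at_one(self):
        good, _, _ = tpe_split(_history(np.linspace(0, 1, 10)), gamma=1e-6)
        assert len(good) == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            tpe_split([], 0.3)
        with pytest.raises(ValueError):
            tpe_split(_history([0.1, 0.2]), 1.5)


class TestParzenDensity:
    def test_single_point_symmetry(self):
        d = parzen_density([1.0], Dimension("x", "real", (0.0, 2.0)))
        for eps in (0.1, 0.3, 0.7):
            assert d.pdf(1.0 - eps) == pytest.approx(d.pdf(1.0 + eps), rel=1e-9)

    def test_categorical_smoothing(self):
        d = parzen_density([4, 4, 4, 8], Dimension("b", "categorical", (4, 8, 16)))
        assert d.probs == pytest.approx([4 / 7, 2 / 7, 1 / 7])

    def test_continuous_density_integrates_to_one(self):
        d = parzen_density([0.5, 1.2, 1.9], Dimension("x", "real", (0.0, 2.0)))
        xs = np.linspace(0, 2, 8001)
        integral = np.trapezoid([d.pdf(x) for x in xs], xs)
        assert integral == pytest.approx(1.0, abs=1e-2)

    def test_log_real_density_integrates_to_one_in_log_space(self):
        d = parzen_density([1e-3, 1e-2], Dimension("lr", "log-real", (1e-4, 0.1)))
        zs = np.linspace(-4, -1, 8001)
        integral = np.trapezoid([d.pdf(10.0**z) for z in zs], zs)
        assert integral == pytest.approx(1.0, abs=1e-2)

    def test_integer_sampling_rounds_into_domain(self, rng):
        d = parzen_density([200, 1500], Dimension("ep", "integer", (200, 2000)))
        s = d.sample(rng, 200)
        assert np.issubdtype(s.dtype, np.integer)
        assert s.min() >= 200 and s.max() <= 2000

    def test_point_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            parzen_density([3.0], Dimension("x", "real", (0.0, 2.0)))


class TestAcquisition:
    class _Const:
        def __init__(self, v):
            self.v = v

        def pdf(self, x):
            return self.v

    def test_closed_forms(self):
        assert tpe_acquisition(0, self._Const(1.0), self._Const(0.0), 0.25) == pytest.approx(4.0)
        assert tpe_acquisition(0, self._Const(0.7), self._Const(0.7), 0.25) == pytest.approx(1.0)

    def test_monotone_decreasing_in_density_ratio(self):
        vals = [
            tpe_acquisition(0, self._Const(1.0), self._Const(g), 0.25)
            for g in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestOptimize:
    LR_SPACE = SearchSpace(dims=(Dimension("lr", "log-real", (1e-4, 0.1)),))

    @staticmethod
    def _quad(conf):
        return (conf["lr"] - 0.01) ** 2

    def test_finds_quadratic_minimum(self):
        hits = 0
        for seed in range(10):
            best, _ = tpe_optimize(self._quad, self.LR_SPACE, n_trials=100,
                                   n_startup=10, seed=seed)
            if 0.005 <= best.config["lr"] <= 0.02:
                hits += 1
        assert hits >= 9

    def test_reduces_to_random_search_without_model_phase(self):
        best, history = tpe_optimize(self._quad, self.LR_SPACE, n_trials=11,
                                     n_startup=10, seed=0)
        assert len(history) == 11

    def test_best_so_far_monotone(self):
        _, history = tpe_optimize(self._quad, self.LR_SPACE, n_trials=40, seed=1)
        running = np.minimum.accumulate([tr.loss for tr in history])
        assert np.all(np.diff(running) <= 0)

    def test_all_samples_in_domain(self):
        space = default_hyperparam_space()
        seen = []

        def obj(conf):
            seen.append(dict(conf))
            return abs(math.log10(conf["learning_rate"]) + 2)

        tpe_optimize(obj, space, n_trials=30, seed=0)
        for conf in seen:
            assert conf["batch_size"] in (4, 8, 16, 32, 64)
            assert 1e-4 <= conf["learning_rate"] <= 0.1
            assert 200 <= conf["epochs"] <= 2000
            assert 0.8 <= conf["momentum"] <= 0.99

    def test_failures_recorded_as_inf(self):
        def flaky(conf):
            if conf["lr"] > 0.01:
                raise RuntimeError("boom")
            return conf["lr"]

        best, history = tpe_optimize(flaky, self.LR_SPACE, n_trials=20, seed=3)
        assert any(math.isinf(tr.loss) for tr in history)
        assert math.isfinite(best.loss)

    def test_beats_uniform_random_search(self):
        """Paired comparison at equal budget on a smooth 2D objective."""
        space = SearchSpace(
            dims=(
                Dimension("a", "real", (-2.0, 2.0)),
                Dimension("b", "real", (-2.0, 2.0)),
            )
        )

        def obj(conf):
            return (conf["a"] - 0.5) ** 2 + (conf["b"] + 0.3) ** 2

        tpe_losses, rnd_losses = [], []
        for seed in range(20):
            best, _ = tpe_optimize(obj, space, n_trials=60, n_startup=10, seed=seed)
            tpe_losses.append(best.loss)
            rng = np.random.default_rng(10_000 + seed)
            rnd_losses.append(
                min(obj({"a": rng.uniform(-2, 2), "b": rng.uniform(-2, 2)}) for _ in range(60))
            )
        assert np.mean(tpe_losses) < np.mean(rnd_losses)
        assert np.mean(np.array(tpe_losses) < np.array(rnd_losses)) >= 0.75

    def test_seed_determinism(self):
        b1, h1 = tpe_optimize(self._quad, self.LR_SPACE, n_trials=25, seed=6)
        b2, h2 = tpe_optimize(self._quad, self.LR_SPACE, n_trials=25, seed=6)
        assert b1.config == b2.config and b1.loss == b2.loss

    def test_budget_validation(self):
        with pytest.raises(ValueError):
            tpe_optimize(self._quad, self.LR_SPACE, n_trials=5, n_startup=5)


class TestSerialization:
    def test_history_round_trip(self):
        history = [
            TrialRecord(config={"lr": 0.01, "batch_size": 8}, loss=0.25, trial_id=0),
            TrialRecord(config={"lr": 0.1, "batch_size": 4}, loss=math.inf, trial_id=1),
        ]
        back = history_from_json(history_to_json(history))
        assert [tr.config for tr in back] == [tr.config for tr in history]
        assert back[0].loss == 0.25 and math.isinf(back[1].loss)
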