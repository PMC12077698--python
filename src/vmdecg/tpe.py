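"""Tree-structured Parzen estimator (TPE) hyperparameter search.

TPE models the conditional densities of configurations given their loss:
``l(x)`` from the trials in the best gamma-fraction of losses and ``g(x)``
from the remainder, and ranks candidates by the acquisition
``(gamma + (g(x)/l(x)) (1 - gamma))^-1`` -- a monotone transform of the
expected improvement.  Each dimension is modelled independently:
continuous dimensions by a truncated-Gaussian mixture (one component per
observation plus a uniform prior component), categorical dimensions by
add-one-smoothed counts, integer dimensions continuously with rounding,
and log-scale dimensions in log10 space (the Jacobian cancels in the
g/l ratio).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Dimension",
    "SearchSpace",
    "TrialRecord",
    "tpe_split",
    "parzen_density",
    "ParzenDensity",
    "CategoricalDensity",
    "tpe_acquisition",
    "tpe_optimize",
    "default_hyperparam_space",
    "history_to_json",
    "history_from_json",
]

_KINDS = ("categorical", "real", "integer", "log-real")


@dataclass(frozen=True)
class Dimension:
    name: str
    kind: str
    domain: tuple  # categories for categorical, (lo, hi) otherwise

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if len(self.domain) == 0:
            raise ValueError("empty domain")
        if self.kind != "categorical":
            lo, hi = self.domain
            if not lo < hi:
                raise ValueError(f"bounds must be ordered, got {self.domain}")
            if self.kind == "log-real" and lo <= 0:
                raise ValueError("log-real dimensions need positive bounds")


@dataclass(frozen=True)
class SearchSpace:
    dims: tuple

    def __iter__(self):
        return iter(self.dims)


def default_hyperparam_space() -> SearchSpace:
    """The four tuned training hyperparameters and their ranges."""
    return SearchSpace(
        dims=(
            Dimension("batch_size", "categorical", (4, 8, 16, 32, 64)),
            Dimension("learning_rate", "log-real", (1e-4, 0.1)),
            Dimension("epochs", "integer", (200, 2000)),
            Dimension("momentum", "real", (0.8, 0.99)),
        )
    )


@dataclass
class TrialRecord:
    config: dict
    loss: float
    trial_id: int


def tpe_split(history, gamma: float):
    """Partition trials into (good, bad) with |good| = max(1, ceil(gamma n)).

    Ties in loss are broken by trial order.  Returns (good, bad, y_star)
    with y_star the empirical gamma-quantile of the finite losses.
    """
    if len(history) == 0:
        raise ValueError("history must be non-empty")
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    n = len(history)
    n_good = max(1, math.ceil(gamma * n))
    order = sorted(history, key=lambda tr: (tr.loss, tr.trial_id))
    good, bad = order[:n_good], order[n_good:]
    finite = [tr.loss for tr in history if math.isfinite(tr.loss)]
    y_star = float(np.quantile(finite, gamma)) if finite else math.inf
    return good, bad, y_star


class ParzenDensity:
    """Truncated-Gaussian mixture over a bounded numeric dimension.

    One component per observed point plus one uniform prior component, all
    equally weighted; bandwidth = domain width / (n_points + 1), floored at
    1% of the width.  ``log`` transforms the working space to log10.
    """

    def __init__(self, points, lo: float, hi: float, log: bool = False, integer: bool = False):
        points = np.asarray(points, dtype=float)
        if points.size == 0:
            raise ValueError("need at least one point")
        if np.any(points < lo) or np.any(points > hi):
            raise ValueError("point outside domain")
        self.log = log
        self.integer = integer
        self._lo_raw, self._hi_raw = lo, hi
        tf = (lambda v: np.log10(v)) if log else (lambda v: np.asarray(v, float))
        self.lo, self.hi = float(tf(lo)), float(tf(hi))
        self.mu = np.atleast_1d(tf(points)).astype(float)
        width = self.hi - self.lo
        self.bw = max(width / (self.mu.size + 1), 0.01 * width)
        a = (self.lo - self.mu) / self.bw
        b = (self.hi - self.mu) / self.bw
        self._norm = stats.norm.cdf(b) - stats.norm.cdf(a)  # truncation mass
        self._w = 1.0 / (self.mu.size + 1)                  # incl. uniform prior

    def pdf(self, x) -> float:
        """Density in the working (possibly log10) space at raw value x."""
        z = math.log10(x) if self.log else float(x)
        if not self.lo <= z <= self.hi:
            return 0.0
        comps = stats.norm.pdf((z - self.mu) / self.bw) / self.bw / self._norm
        return float(self._w * (comps.sum() + 1.0 / (self.hi - self.lo)))

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        comp = rng.integers(0, self.mu.size + 1, size)
        z = np.empty(size)
        for i, c in enumerate(comp):
            if c == self.mu.size:
                z[i] = rng.uniform(self.lo, self.hi)
            else:
                while True:
                    v = rng.normal(self.mu[c], self.bw)
                    if self.lo <= v <= self.hi:
                        z[i] = v
                        break
        x = 10.0**z if self.log else z
        if self.integer:
            x = np.clip(np.round(x), self._lo_raw, self._hi_raw).astype(int)
        return x


class CategoricalDensity:
    """Add-one-smoothed category probabilities."""

    def __init__(self, points, categories):
        self.categories = list(categories)
        idx = {c: i for i, c in enumerate(self.categories)}
        for p in points:
            if p not in idx:
                raise ValueError(f"point {p!r} outside domain")
        counts = np.zeros(len(self.categories))
        for p in points:
            counts[idx[p]] += 1
        self.probs = (counts + 1.0) / (counts.sum() + len(self.categories))
        self._idx = idx

    def pdf(self, x) -> float:
        return float(self.probs[self._idx[x]])

    def sample(self, rng: np.random.Generator, size: int = 1):
        picks = rng.choice(len(self.categories), size=size, p=self.probs)
        return np.array([self.categories[i] for i in picks], dtype=object)


def parzen_density(points, dim: Dimension):
    """Density estimator + sampler for one search-space dimension."""
    if dim.kind == "categorical":
        return CategoricalDensity(points, dim.domain)
    lo, hi = dim.domain
    return ParzenDensity(
        points, lo, hi, log=(dim.kind == "log-real"), integer=(dim.kind == "integer")
    )


def tpe_acquisition(x, l_density, g_density, gamma: float) -> float:
    """(gamma + (g(x)/l(x)) (1 - gamma))^-1, larger is better."""
    lx = max(l_density.pdf(x), 1e-300)
    gx = g_density.pdf(x)
    return 1.0 / (gamma + (gx / lx) * (1.0 - gamma))


def _uniform_sample(dim: Dimension, rng) -> object:
    if dim.kind == "categorical":
        return dim.domain[rng.integers(0, len(dim.domain))]
    lo, hi = dim.domain
    if dim.kind == "log-real":
        return float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))
    if dim.kind == "integer":
        return int(rng.integers(lo, hi + 1))
    return float(rng.uniform(lo, hi))


def tpe_optimize(
    objective,
    space: SearchSpace,
    n_trials: int = 50,
    n_startup: int = 10,
    n_candidates: int = 24,
    gamma: float = 0.25,
    seed: int = 0,
):
    """Sequential TPE minimization of ``objective(config) -> loss``.

    The first ``n_startup`` trials are drawn uniformly; afterwards each
    trial samples ``n_candidates`` configurations from the good-trial
    density l and evaluates the one maximizing the acquisition.  A failing
    objective records loss = +inf (such trials never enter l).  Returns
    ``(best TrialRecord, history)``.
    """
    if not n_trials > n_startup >= 2:
        raise ValueError("need n_trials > n_startup >= 2")
    rng = np.random.default_rng(seed)
    history: list[TrialRecord] = []
    for t in range(n_trials):
        if t < n_startup:
            config = {d.name: _uniform_sample(d, rng) for d in space}
        else:
            usable = [tr for tr in history if math.isfinite(tr.loss)]
            good, bad, _ = tpe_split(usable if usable else history, gamma)
            if not bad:  # everything is "good"; fall back to uniform
                config = {d.name: _uniform_sample(d, rng) for d in space}
            else:
                l_d = {d.name: parzen_density([tr.config[d.name] for tr in good], d) for d in space}
                g_d = {d.name: parzen_density([tr.config[d.name] for tr in bad], d) for d in space}
                best_score, config = -math.inf, None
                for _ in range(n_candidates):
                    cand = {d.name: l_d[d.name].sample(rng, 1)[0] for d in space}
                    score = 1.0
                    for d in space:
                        score *= tpe_acquisition(cand[d.name], l_d[d.name], g_d[d.name], gamma)
                    if score > best_score:
                        best_score, config = score, cand
        try:
            loss = float(objective(config))
            if not math.isfinite(loss):
                loss = math.inf
        except Exception:
            loss = math.inf
        history.append(TrialRecord(config=dict(config), loss=loss, trial_id=t))
    best = min(history, key=lambda tr: (tr.loss, tr.trial_id))
    return best, history


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def history_to_json(history) -> str:
    return json.dumps(
        [
            {
                "trial_id": tr.trial_id,
                "loss": (None if not math.isfinite(tr.loss) else tr.loss),
                "config": {k: _jsonify(v) for k, v in tr.config.items()},
            }
            for tr in history
        ]
    )


def history_from_json(text: str):
    return [
        TrialRecord(
            config=d["config"],
            loss=(math.inf if d["loss"] is None else float(d["loss"])),
            trial_id=int(d["trial_id"]),
        )
        for d in json.loads(text)
    ]
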