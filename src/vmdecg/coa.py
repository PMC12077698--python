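"""Crayfish optimization (COA) and its multi-objective extension (MOCOA).

COA is a population metaheuristic whose moves are gated by a random ambient
temperature drawn per individual each generation, ``temp = 15 rand + 20``:

* temp > 30, rand < 0.5  -- "summer resort": drift toward the cave
  ``X_shade = (X_G + X_L) / 2`` (global-best and population-best midpoint)
  scaled by the decreasing coefficient ``C2 = 2 - t/T``;
* temp > 30, rand >= 0.5 -- "competition": ``X - X_z + X_shade`` against a
  random peer z;
* temp <= 30             -- "foraging": intake ``p`` follows a Gaussian
  curve peaking at the ideal temperature mu = 25; food size
  ``Q = C3 rand (fitness_i / fitness_food)`` decides between tearing the
  food (``X_food`` shrunk by exp(-1/Q), then an oscillatory approach) and
  eating directly.

New positions are clipped to the bounds and kept only when they improve the
individual (greedy retention).  The multi-objective variant advances the
parent population once per objective, pools the k*N candidates, applies
fast non-dominated sorting, and truncates by the special crowding distance
that combines decision-space and objective-space crowding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "COAConfig",
    "Individual",
    "ParetoFront",
    "ackley",
    "coa_minimize",
    "dominates",
    "fast_non_dominated_sort",
    "crowding_distance",
    "special_crowding_distance",
    "mocoa",
    "hypervolume_2d",
]


@dataclass(frozen=True)
class COAConfig:
    """Optimizer configuration; bounds are per-dimension (lb, ub) arrays."""

    N: int = 50
    T: int = 200
    lb: tuple = (-32.0, -32.0)
    ub: tuple = (32.0, 32.0)
    mu: float = 25.0
    sigma: float = 3.0
    C1: float = 0.2
    C3: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if self.T < 1:
            raise ValueError("iteration count T must be >= 1")
        lb, ub = np.asarray(self.lb, float), np.asarray(self.ub, float)
        if lb.shape != ub.shape or np.any(lb >= ub):
            raise ValueError("require lb < ub elementwise")

    def C2(self, t: int) -> float:
        """Decreasing coefficient 2 - t/T."""
        return 2.0 - t / self.T

    @property
    def dim(self) -> int:
        return len(self.lb)


@dataclass
class Individual:
    position: np.ndarray
    fitness: np.ndarray      # length = number of objectives (1 for COA)
    rank: int = 1
    scd: float = math.inf


@dataclass
class ParetoFront:
    """A mutually non-dominated set of rank-1 individuals."""

    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        fits = [m.fitness for m in self.members]
        for i, u in enumerate(fits):
            for j, v in enumerate(fits):
                if i != j and dominates(u, v):
                    raise ValueError("front members must be mutually non-dominated")

    def positions(self) -> np.ndarray:
        return np.stack([m.position for m in self.members])

    def fitnesses(self) -> np.ndarray:
        return np.stack([m.fitness for m in self.members])


def ackley(x, a: float = 20.0, b: float = 0.2, c: float = 2.0 * math.pi) -> float:
    """Ackley benchmark; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("ackley requires a non-empty vector")
    d = x.size
    # grouped so both terms cancel exactly at the optimum
    t1 = a - a * math.exp(-b * math.sqrt(np.sum(x**2) / d))
    t2 = math.e - math.exp(np.sum(np.cos(c * x)) / d)
    return float(t1 + t2)


def _evaluate(objective, X: np.ndarray) -> np.ndarray:
    vals = np.array([objective(row) for row in X], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = X[np.flatnonzero(~np.isfinite(vals))[0]]
        raise FloatingPointError(f"objective returned non-finite value at {bad}")
    return vals


def _coa_move(X, fit, X_food, fit_food, X_L, C2, cfg: COAConfig, rng) -> np.ndarray:
    """One COA position update of the whole population, guided by one objective."""
    N, dim = X.shape
    Xnew = np.empty_like(X)
    temp = rng.uniform(0, 1, N) * 15.0 + 20.0
    X_shade = (X_food + X_L) / 2.0
    fden = fit_food if abs(fit_food) > 1e-12 else math.copysign(1e-12, fit_food or 1.0)
    hot = temp > 30.0
    branch = rng.uniform(0, 1, N)
    for i in range(N):
        if hot[i]:
            if branch[i] < 0.5:
                Xnew[i] = X[i] + C2 * rng.uniform(0, 1, dim) * (X_shade - X[i])
            else:
                z = int(round(rng.uniform(0, 1) * (N - 1)))
                Xnew[i] = X[i] - X[z] + X_shade
        else:
            p = cfg.C1 * (1.0 / (math.sqrt(2.0 * math.pi) * cfg.sigma)) * math.exp(
                -((temp[i] - cfg.mu) ** 2) / (2.0 * cfg.sigma**2)
            )
            Q = cfg.C3 * rng.uniform(0, 1) * (fit[i] / fden)
            if Q > (cfg.C3 + 1.0) / 2.0:
                food = math.exp(-1.0 / Q) * X_food
                Xnew[i] = X[i] + food * p * (
                    math.cos(2.0 * math.pi * rng.uniform(0, 1))
                    - math.sin(2.0 * math.pi * rng.uniform(0, 1))
                )
            else:
                Xnew[i] = (X[i] - X_food) * p + p * rng.uniform(0, 1) * X[i]
    lb, ub = np.asarray(cfg.lb, float), np.asarray(cfg.ub, float)
    return np.clip(Xnew, lb, ub)


def coa_minimize(objective, config: COAConfig):
    """Single-objective COA.  Returns (best Individual, best-per-iteration history)."""
    rng = np.random.default_rng(config.seed)
    lb, ub = np.asarray(config.lb, float), np.asarray(config.ub, float)
    X = lb + (ub - lb) * rng.uniform(0, 1, (config.N, config.dim))
    fit = _evaluate(objective, X)
    ib = int(np.argmin(fit))
    X_food, fit_food = X[ib].copy(), float(fit[ib])
    history = []
    for t in range(1, config.T + 1):
        X_L = X[int(np.argmin(fit))]
        Xc = _coa_move(X, fit, X_food, fit_food, X_L, config.C2(t), config, rng)
        fc = _evaluate(objective, Xc)
        better = fc < fit
        X[better] = Xc[better]
        fit[better] = fc[better]
        ib = int(np.argmin(fit))
        if fit[ib] < fit_food:
            X_food, fit_food = X[ib].copy(), float(fit[ib])
        history.append(fit_food)
    best = Individual(position=X_food, fitness=np.array([fit_food]))
    return best, np.asarray(history)


# ---------------------------------------------------------------------------
# Pareto machinery


def dominates(u, v) -> bool:
    """True iff u is no worse in every objective and strictly better in one."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(u <= v) and np.any(u < v))


def fast_non_dominated_sort(fitnesses):
    """NSGA-II fast non-dominated sort.

    Returns ``(ranks, fronts)``: 1-based rank per element and a list of
    index lists, fronts[0] being the non-dominated set.
    """
    F = np.asarray(fitnesses, dtype=float)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("need a non-empty list of equal-length objective vectors")
    n = F.shape[0]
    # pairwise dominance via broadcasting
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    ranks = np.zeros(n, dtype=int)
    fronts = []
    current = np.flatnonzero(n_dominators == 0)
    r = 1
    remaining = n_dominators.astype(int)
    while current.size:
        ranks[current] = r
        fronts.append(current.tolist())
        for i in current:
            remaining[dom[i]] -= 1
        remaining[current] = -1
        current = np.flatnonzero(remaining == 0)
        r += 1
    return ranks, fronts


def crowding_distance(front_values) -> np.ndarray:
    """Per-member crowding distance within one front.

    ``front_values``: (n, d) coordinates (objective- or decision-space).
    Interior members accumulate the normalized neighbor gap per dimension;
    boundary members get +inf; zero-range dimensions contribute nothing.
    """
    V = np.atleast_2d(np.asarray(front_values, dtype=float))
    n, d = V.shape
    if n == 0:
        raise ValueError("front must have at least one member")
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(d):
        order = np.argsort(V[:, j], kind="stable")
        vj = V[order, j]
        span = vj[-1] - vj[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            interior = order[1:-1]
            gaps = (vj[2:] - vj[:-2]) / span
            finite = np.isfinite(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def special_crowding_distance(cd_x: float, cd_f: float, avg_x: float, avg_f: float) -> float:
    """Combine decision- and objective-space crowding into one score.

    Takes the max of the two crowdings when either exceeds its front
    average (keep well-spread individuals), otherwise the min.
    """
    if cd_x > avg_x or cd_f > avg_f:
        return max(cd_x, cd_f)
    return min(cd_x, cd_f)


def _scd_for_front(positions, fitness) -> np.ndarray:
    cd_x = crowding_distance(positions)
    cd_f = crowding_distance(fitness)

    def _avg(a):
        fin = a[np.isfinite(a)]
        return float(fin.mean()) if fin.size else math.inf

    ax, af = _avg(cd_x), _avg(cd_f)
    return np.array(
        [special_crowding_distance(cd_x[i], cd_f[i], ax, af) for i in range(len(cd_x))]
    )


def mocoa(objectives, config: COAConfig):
    """Multi-objective COA.

    ``objectives``: list of k >= 2 scalar objective callables.  Each
    generation the parent population is advanced once per objective (COA
    move guided by that objective's best-so-far food position), the pooled
    k*N candidates are evaluated on all objectives, non-dominated sorted,
    ranked within fronts by special crowding distance and truncated back to
    N.  Returns ``(ParetoFront, history)`` where history records the rank-1
    front size per generation.
    """
    k = len(objectives)
    if k < 2:
        raise ValueError("mocoa needs >= 2 objectives; use coa_minimize")
    rng = np.random.default_rng(config.seed)
    lb, ub = np.asarray(config.lb, float), np.asarray(config.ub, float)
    X = lb + (ub - lb) * rng.uniform(0, 1, (config.N, config.dim))
    F = np.column_stack([_evaluate(obj, X) for obj in objectives])

    foods = [X[int(np.argmin(F[:, j]))].copy() for j in range(k)]
    food_fits = [float(F[:, j].min()) for j in range(k)]
    history = []
    for t in range(1, config.T + 1):
        pool_X, pool_F = [], []
        for j in range(k):
            X_L = X[int(np.argmin(F[:, j]))]
            Xc = _coa_move(X, F[:, j], foods[j], food_fits[j], X_L, config.C2(t), config, rng)
            Fc = np.column_stack([_evaluate(obj, Xc) for obj in objectives])
            pool_X.append(Xc)
            pool_F.append(Fc)
        allX = np.vstack(pool_X)
        allF = np.vstack(pool_F)
        # deduplicate identical candidates to keep the pool diverse
        _, uniq = np.unique(np.round(allX, 12), axis=0, return_index=True)
        allX, allF = allX[np.sort(uniq)], allF[np.sort(uniq)]

        ranks, fronts = fast_non_dominated_sort(allF)
        keep = []
        for front in fronts:
            front = np.asarray(front)
            if len(keep) + front.size <= config.N:
                keep.extend(front.tolist())
            else:
                scd = _scd_for_front(allX[front], allF[front])
                order = np.argsort(-scd, kind="stable")
                keep.extend(front[order[: config.N - len(keep)]].tolist())
            if len(keep) >= config.N:
                break
        keep = np.asarray(keep[: config.N])
        X, F = allX[keep], allF[keep]
        for j in range(k):
            jb = int(np.argmin(allF[:, j]))
            if allF[jb, j] < food_fits[j]:
                foods[j] = allX[jb].copy()
                food_fits[j] = float(allF[jb, j])
        history.append(int(np.sum(fast_non_dominated_sort(F)[0] == 1)))

    ranks, fronts = fast_non_dominated_sort(F)
    first = np.asarray(fronts[0])
    scd = _scd_for_front(X[first], F[first])
    members = [
        Individual(position=X[i].copy(), fitness=F[i].copy(), rank=1, scd=float(s))
        for i, s in zip(first, scd)
    ]
    return ParetoFront(members=members), history


def hypervolume_2d(points, ref) -> float:
    """Hypervolume (area dominated w.r.t. ``ref``) of a 2-objective set."""
    P = np.asarray(points, dtype=float)
    rx, ry = ref
    P = P[(P[:, 0] <= rx) & (P[:, 1] <= ry)]
    if P.size == 0:
        return 0.0
    P = P[np.lexsort((P[:, 1], P[:, 0]))]
    hv, prev_y = 0.0, ry
    for x, y in P:
        if y < prev_y:
            hv += (rx - x) * (prev_y - y)
            prev_y = y
    return hv
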