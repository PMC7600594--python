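"""Four population metaheuristics behind one bounded minimization interface.

Differential Search (DS), the Shuffled Frog Leaping Algorithm (SFLA),
Wolf Search (WS, the grey-wolf alpha/beta/delta update), and Animal
Migration Optimization (AMO) all minimize a scalar fitness over a box
``[lower, upper]^D``.  Every run is bit-reproducible from its seed, and
the best-so-far fitness trace is non-increasing by construction.

Applied to code-word streams, the fitness is one-dimensional vector
quantization distortion: a candidate x (length D) scores the mean squared
distance of each stream value to its nearest component of x, which is
zero exactly when every stream value coincides with some representative —
the "singleton pattern" the optimization stage drives toward.  The stream
itself is seeded as one population member, so the optimized result can
never be worse than the raw reduced vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List

import numpy as np

from .codewords import VALUE_MAX, PatientCodeStream, reduce_stream

ALGORITHMS = ("DS", "SFLA", "WS", "AMO")

Fitness = Callable[[np.ndarray], float]


class OptimizerConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SearchSpace:
    """A box-bounded continuous search domain."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise OptimizerConfigError("lower/upper must be 1-D and same shape")
        if not np.all(lower < upper):
            raise OptimizerConfigError("lower must be < upper elementwise")

    @property
    def dimension(self) -> int:
        return self.lower.size

    @classmethod
    def cube(cls, d: int, lo: float, hi: float) -> "SearchSpace":
        return cls(np.full(d, lo), np.full(d, hi))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass(frozen=True)
class OptimizerConfig:
    """Configuration shared by the four algorithms.

    ``np_size`` is the population size NP; ``max_iter`` the iteration
    (DS/WS/AMO) or shuffle (SFLA) budget.  Algorithm-specific knobs:
    DS mask rates p1/p2 (None -> 0.3*rand drawn per run), SFLA memeplex
    layout z x y with step clamp Rmax and a stall limit, AMO ring
    neighborhood half-width.
    """

    algorithm: str = "DS"
    np_size: int = 20
    max_iter: int = 200
    seed: int = 0
    ds_p1: float | None = None
    ds_p2: float | None = None
    sfla_memeplexes: int = 4
    sfla_frogs_per_memeplex: int = 5
    sfla_rmax: float = 0.5
    sfla_local_iters: int = 15
    sfla_stall_limit: int = 50
    amo_neighborhood_halfwidth: int = 2

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise OptimizerConfigError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if self.np_size < 4:
            raise OptimizerConfigError("np_size must be >= 4")
        if self.max_iter < 1:
            raise OptimizerConfigError("max_iter must be >= 1")
        for name in ("ds_p1", "ds_p2"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise OptimizerConfigError(f"{name} must be in [0, 1]")
        if self.algorithm == "SFLA":
            if self.sfla_memeplexes * self.sfla_frogs_per_memeplex != self.np_size:
                raise OptimizerConfigError(
                    "SFLA requires np_size = memeplexes x frogs_per_memeplex"
                )
        if self.amo_neighborhood_halfwidth < 1:
            raise OptimizerConfigError("amo_neighborhood_halfwidth must be >= 1")


@dataclass
class OptResult:
    """Best solution and per-iteration best-so-far trace."""

    best_position: np.ndarray
    best_fitness: float
    fitness_trace: List[float]
    evaluations: int


class QuantizationFitness:
    """Mean squared distance of stream values to their nearest candidate.

    fitness(x) = (1/n) sum_i min_j (v_i - x_j)^2; zero iff every value
    equals some component of x.
    """

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float).ravel()
        if self.data.size == 0:
            raise ValueError("data is empty")

    def __call__(self, x: np.ndarray) -> float:
        d = self.data[:, None] - np.asarray(x, dtype=float)[None, :]
        return float(np.min(d * d, axis=1).mean())


def init_population(
    space: SearchSpace, np_size: int, seed_or_rng: int | np.random.Generator
) -> np.ndarray:
    """NP x D matrix uniform within the bounds; deterministic given seed."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    d = space.dimension
    return space.lower + rng.random((np_size, d)) * (space.upper - space.lower)


class _Tracker:
    """Keeps the best-so-far solution and the non-increasing trace."""

    def __init__(self) -> None:
        self.best_x: np.ndarray | None = None
        self.best_f = np.inf
        self.trace: List[float] = []
        self.evals = 0

    def eval(self, fitness: Fitness, x: np.ndarray) -> float:
        f = float(fitness(x))
        self.evals += 1
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x)
        return f

    def tick(self) -> None:
        self.trace.append(self.best_f)

    def result(self) -> OptResult:
        assert self.best_x is not None
        return OptResult(self.best_x, self.best_f, self.trace, self.evals)


def _setup(
    fitness: Fitness,
    space: SearchSpace,
    cfg: OptimizerConfig,
    x0: np.ndarray | None,
):
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(space, cfg.np_size, rng)
    if x0 is not None:
        pop[0] = space.clip(np.asarray(x0, dtype=float))
    tracker = _Tracker()
    fit = np.array([tracker.eval(fitness, ind) for ind in pop])
    return rng, pop, fit, tracker


# ---------------------------------------------------------------------------
# Differential Search
# ---------------------------------------------------------------------------


def _ds_mask(rng: np.random.Generator, np_size: int, d: int, p1: float, p2: float) -> np.ndarray:
    """Mutation map: True where the trial takes the stopover coordinate."""
    mask = np.zeros((np_size, d), dtype=bool)
    if rng.random() < rng.random():
        if rng.random() < p1:
            for z in range(np_size):
                mask[z] = rng.random(d) < rng.random()
        else:
            mask[np.arange(np_size), rng.integers(0, d, np_size)] = True
    else:
        for z in range(np_size):
            k = max(1, int(np.ceil(p2 * rng.random() * d)))
            mask[z, rng.choice(d, size=min(k, d), replace=False)] = True
    # a row with no active coordinate would clone its parent; activate one
    empty = ~mask.any(axis=1)
    if empty.any():
        mask[np.where(empty)[0], rng.integers(0, d, int(empty.sum()))] = True
    return mask


def run_ds(
    fitness: Fitness,
    space: SearchSpace,
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> OptResult:
    """Differential Search: Brownian-like stopover walk with greedy selection."""
    rng, pop, fit, tracker = _setup(fitness, space, cfg, x0)
    np_size, d = pop.shape
    p1 = cfg.ds_p1 if cfg.ds_p1 is not None else 0.3 * rng.random()
    p2 = cfg.ds_p2 if cfg.ds_p2 is not None else 0.3 * rng.random()

    for _ in range(cfg.max_iter):
        scale = rng.gamma(max(2 * rng.random(), 1e-12), 1.0) * (
            rng.random() - rng.random()
        )
        partners = rng.integers(0, np_size - 1, np_size)
        partners[partners >= np.arange(np_size)] += 1  # r1 != z
        stopover = pop + scale * (pop[partners] - pop)
        mask = _ds_mask(rng, np_size, d, p1, p2)
        trial = np.where(mask, stopover, pop)
        # out-of-bounds coordinates are re-drawn uniformly in bounds
        oob = (trial < space.lower) | (trial > space.upper)
        if oob.any():
            redraw = space.lower + rng.random((np_size, d)) * (
                space.upper - space.lower
            )
            trial = np.where(oob, redraw, trial)
        for z in range(np_size):
            f = tracker.eval(fitness, trial[z])
            if f <= fit[z]:
                pop[z], fit[z] = trial[z], f
        tracker.tick()
    return tracker.result()


# ---------------------------------------------------------------------------
# Shuffled Frog Leaping
# ---------------------------------------------------------------------------


def deal_memeplexes(order: np.ndarray, z: int) -> List[np.ndarray]:
    """Round-robin deal of fitness-ranked indices into z memeplexes.

    ``order`` lists population indices best-first; memeplex m receives
    ranks m, m+z, m+2z, ...
    """
    return [order[m::z] for m in range(z)]


def run_sfla(
    fitness: Fitness,
    space: SearchSpace,
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> OptResult:
    """SFLA: memeplex-local worst-frog improvement with periodic shuffles."""
    if cfg.sfla_memeplexes * cfg.sfla_frogs_per_memeplex != cfg.np_size:
        raise OptimizerConfigError(
            "SFLA requires np_size = memeplexes x frogs_per_memeplex"
        )
    rng, pop, fit, tracker = _setup(fitness, space, cfg, x0)
    z = cfg.sfla_memeplexes
    rmax = cfg.sfla_rmax * np.max(space.upper - space.lower)
    stall = 0
    for _ in range(cfg.max_iter):
        before = tracker.best_f
        order = np.argsort(fit, kind="stable")  # best first (minimization)
        plexes = deal_memeplexes(order, z)
        g = order[0]
        for plex in plexes:
            for _ in range(cfg.sfla_local_iters):
                b = plex[np.argmin(fit[plex])]
                w = plex[np.argmax(fit[plex])]
                improved = False
                for leader in (b, g):
                    step = rng.random() * (pop[leader] - pop[w])
                    step = np.clip(step, -rmax, rmax)
                    cand = pop[w] + step
                    if np.all(cand >= space.lower) and np.all(cand <= space.upper):
                        f = tracker.eval(fitness, cand)
                        if f < fit[w]:
                            pop[w], fit[w] = cand, f
                            improved = True
                            break
                if not improved:
                    cand = init_population(space, 1, rng)[0]
                    pop[w] = cand
                    fit[w] = tracker.eval(fitness, cand)
                if fit[w] < fit[g]:
                    g = w
        tracker.tick()
        stall = stall + 1 if tracker.best_f >= before else 0
        if stall >= cfg.sfla_stall_limit:
            break
    return tracker.result()


# ---------------------------------------------------------------------------
# Wolf Search (grey-wolf update)
# ---------------------------------------------------------------------------


def ws_alpha_schedule(iteration: int, max_iter: int) -> float:
    """Control parameter declining linearly from 2 (iteration 0) to 0."""
    return 2.0 * (1.0 - iteration / max_iter)


def run_ws(
    fitness: Fitness,
    space: SearchSpace,
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> OptResult:
    """Wolf search: agents average pursuit of the three best solutions."""
    rng, pop, fit, tracker = _setup(fitness, space, cfg, x0)
    np_size, d = pop.shape
    if np_size < 3:
        raise OptimizerConfigError("WS needs np_size >= 3")

    def leaders():
        order = np.argsort(fit, kind="stable")
        return [np.array(pop[i]) for i in order[:3]], [fit[i] for i in order[:3]]

    (pa, pb, pd_), (fa, fb, fd) = leaders()
    for t in range(cfg.max_iter):
        a = ws_alpha_schedule(t, cfg.max_iter)
        new_pop = np.empty_like(pop)
        for z in range(np_size):
            p = np.zeros(d)
            for lead in (pa, pb, pd_):
                x_coef = 2 * a * rng.random(d) - a
                y_coef = 2 * rng.random(d)
                dist = np.abs(y_coef * lead - pop[z])
                p += lead - x_coef * dist
            new_pop[z] = space.clip(p / 3.0)
        pop = new_pop
        for z in range(np_size):
            fit[z] = tracker.eval(fitness, pop[z])
            # historical alpha/beta/delta update
            if fit[z] < fa:
                pd_, fd = pb, fb
                pb, fb = pa, fa
                pa, fa = np.array(pop[z]), fit[z]
            elif fit[z] < fb:
                pd_, fd = pb, fb
                pb, fb = np.array(pop[z]), fit[z]
            elif fit[z] < fd:
                pd_, fd = np.array(pop[z]), fit[z]
        tracker.tick()
    return tracker.result()


# ---------------------------------------------------------------------------
# Animal Migration Optimization
# ---------------------------------------------------------------------------


def ring_neighborhood(
    index: int, np_size: int, halfwidth: int = 2, one_based: bool = False
) -> List[int]:
    """Ring-topology neighborhood of an individual (wrap-around indices)."""
    if one_based:
        return [
            (index - 1 + off) % np_size + 1 for off in range(-halfwidth, halfwidth + 1)
        ]
    return [(index + off) % np_size for off in range(-halfwidth, halfwidth + 1)]


def amo_replacement_probability(fitness_values: np.ndarray) -> np.ndarray:
    """Pa by fitness rank: worst individual 1, best 1/NP."""
    n = fitness_values.size
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(fitness_values, kind="stable")] = np.arange(1, n + 1)
    return ranks / n


def run_amo(
    fitness: Fitness,
    space: SearchSpace,
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> OptResult:
    """AMO: ring-neighborhood migration then rank-gated population update."""
    rng, pop, fit, tracker = _setup(fitness, space, cfg, x0)
    np_size, d = pop.shape
    if np_size < 5:
        raise OptimizerConfigError("AMO needs np_size >= 5")
    hw = cfg.amo_neighborhood_halfwidth

    for _ in range(cfg.max_iter):
        # migration: move toward a random ring neighbor with Gaussian step
        for j in range(np_size):
            neigh = ring_neighborhood(j, np_size, hw)
            neigh = [i for i in neigh if i != j]
            pick = neigh[rng.integers(0, len(neigh))]
            delta = rng.standard_normal(d)
            cand = space.clip(pop[j] + delta * (pop[pick] - pop[j]))
            f = tracker.eval(fitness, cand)
            if f <= fit[j]:
                pop[j], fit[j] = cand, f
        # population update gated by per-rank replacement probability
        pa = amo_replacement_probability(fit)
        best = pop[np.argmin(fit)].copy()
        for j in range(np_size):
            r1 = rng.integers(0, np_size)
            while r1 == j:
                r1 = rng.integers(0, np_size)
            r2 = rng.integers(0, np_size)
            while r2 == j or r2 == r1:
                r2 = rng.integers(0, np_size)
            gate = rng.random(d) > pa[j]
            if gate.any():
                cand = pop[j].copy()
                upd = (
                    pop[r1]
                    + rng.random(d) * (best - pop[j])
                    + rng.random(d) * (pop[r2] - pop[j])
                )
                cand[gate] = upd[gate]
                cand = space.clip(cand)
                f = tracker.eval(fitness, cand)
                if f <= fit[j]:
                    pop[j], fit[j] = cand, f
        tracker.tick()
    return tracker.result()


_RUNNERS = {"DS": run_ds, "SFLA": run_sfla, "WS": run_ws, "AMO": run_amo}


def run(
    fitness: Fitness,
    space: SearchSpace,
    cfg: OptimizerConfig,
    x0: np.ndarray | None = None,
) -> OptResult:
    """Dispatch to the configured algorithm."""
    cfg.validate()
    return _RUNNERS[cfg.algorithm](fitness, space, cfg, x0)


def random_search(
    fitness: Fitness, space: SearchSpace, n_evals: int, seed: int
) -> OptResult:
    """Uniform random sampling baseline with the same interface."""
    rng = np.random.default_rng(seed)
    tracker = _Tracker()
    for _ in range(n_evals):
        x = init_population(space, 1, rng)[0]
        tracker.eval(fitness, x)
        tracker.tick()
    return tracker.result()


def optimize_stream(
    stream: PatientCodeStream | np.ndarray,
    cfg: OptimizerConfig,
    L: int = 375,
    value_max: float = VALUE_MAX,
) -> np.ndarray:
    """Optimize a patient's reduced code-value vector toward a singleton set.

    Accepts either a code stream (reduced internally to length ``L``) or a
    ready value vector.  The vector itself seeds the population, so the
    returned best position never scores worse than the input.
    """
    if isinstance(stream, PatientCodeStream):
        values = reduce_stream(stream, L)
    else:
        values = np.asarray(stream, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("stream is empty")
    space = SearchSpace.cube(values.size, 0.0, value_max)
    fitness = QuantizationFitness(values)
    result = run(fitness, space, cfg, x0=values)
    return result.best_position
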