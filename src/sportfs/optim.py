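"""Artificial raindrop optimizer with opposition-based learning.

The artificial raindrop algorithm (ARA) is a population metaheuristic in
which candidate solutions ("raindrops") carry their objective value as
potential energy and flow toward a fixed-capacity elite pool of the best
solutions seen so far.  Each iteration a raindrop takes up to ``max_flow``
flow steps — moving a uniform random per-dimension fraction of the distance
toward a rank-biased pool member — followed by a Gaussian perturbation whose
scale shrinks with the adaptive flow coefficient

    beta_{t+1} = beta_t * (1 - t / T),

shifting search from global to local.  Opposition-based learning (OBL)
evaluates the bound-reflected inverse point

    c'_i = b_i + d_i - c_i

of every newly generated raindrop and keeps the fitter of the pair (ties
keep the original).  A raindrop whose fitness fails to improve for more than
``max_stagnation`` consecutive iterations is replaced by its inverse point.
The pool is updated by a bubble pass: a candidate better than the current
worst displaces it and sinks to its sorted position.

The module also provides the Ackley and Rastrigin test functions, plain-ARA /
differential-evolution / inertia-weight-PSO baselines, and a comparison
harness that runs all four under equal iteration budgets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SearchSpace",
    "Raindrop",
    "RaindropPool",
    "FlowState",
    "OptimizerConfig",
    "ConvergenceTrace",
    "ackley",
    "rastrigin",
    "inverse_point",
    "obl_select",
    "update_flow_coefficient",
    "update_pool",
    "gaussian_perturb",
    "optimize",
    "differential_evolution",
    "particle_swarm",
    "compare_optimizers",
]


# -- search space and benchmark functions ----------------------------------


@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box: per-dimension lower and upper bounds."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        hi = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != hi.shape:
            raise ValueError("lower and upper bounds must share a shape")
        if not np.all(lo < hi):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchSpace":
        return cls(np.full(dim, lo), np.full(dim, hi))

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def sample(self, rng, n: int) -> np.ndarray:
        return self.lower + rng.random((n, self.dim)) * self.width


def ackley(x, a: float = 20.0, b: float = 0.2, c: float = 2.0 * np.pi):
    """Standard Ackley function; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    s1 = np.sum(x * x, axis=-1) / d
    s2 = np.sum(np.cos(c * x), axis=-1) / d
    return -a * np.exp(-b * np.sqrt(s1)) - np.exp(s2) + a + np.e


def rastrigin(x, A: float = 10.0):
    """Standard Rastrigin function; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=float)
    d = x.shape[-1]
    return A * d + np.sum(x * x - A * np.cos(2.0 * np.pi * x), axis=-1)


ACKLEY_SPACE = SearchSpace.cube(10, -32.768, 32.768)
RASTRIGIN_SPACE = SearchSpace.cube(10, -5.12, 5.12)


# -- elementary mechanics --------------------------------------------------


def inverse_point(c, space: SearchSpace) -> np.ndarray:
    """Bound-reflected opposite point ``c'_i = b_i + d_i - c_i``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < space.lower - 1e-12) or np.any(c > space.upper + 1e-12):
        warnings.warn(
            "point outside the search space; clamping before reflection",
            RuntimeWarning,
            stacklevel=2,
        )
        c = space.clip(c)
    return space.lower + space.upper - c


def obl_select(c, space: SearchSpace, objective):
    """Keep the fitter of a point and its inverse (ties keep the original)."""
    c = np.asarray(c, dtype=float)
    c_inv = inverse_point(c, space)
    fc = float(objective(c))
    fi = float(objective(c_inv))
    for point, val in ((c, fc), (c_inv, fi)):
        if not np.isfinite(val):
            raise ValueError(f"objective returned non-finite value {val!r} at {point}")
    return (c_inv, fi) if fi < fc else (c, fc)


@dataclass
class FlowState:
    """Adaptive flow coefficient schedule state."""

    beta: float
    t: int
    T: int


def update_flow_coefficient(state: FlowState) -> FlowState:
    """Advance one step of ``beta_{t+1} = beta_t * (1 - t/T)``."""
    if state.T < 1:
        raise ValueError("T must be >= 1")
    if not 0 <= state.t <= state.T:
        raise ValueError("t must lie in [0, T]")
    return FlowState(beta=state.beta * (1.0 - state.t / state.T),
                     t=state.t + 1, T=state.T)


@dataclass
class Raindrop:
    """Candidate solution with its potential energy and stagnation counter."""

    position: np.ndarray
    energy: float
    stagnation: int = 0


class RaindropPool:
    """Fixed-capacity elite archive kept sorted ascending by potential energy."""

    def __init__(self, positions: np.ndarray, energies: np.ndarray):
        order = np.argsort(energies, kind="stable")
        self.positions = np.asarray(positions, dtype=float)[order].copy()
        self.energies = np.asarray(energies, dtype=float)[order].copy()

    @property
    def capacity(self) -> int:
        return self.energies.size

    @property
    def best_energy(self) -> float:
        return float(self.energies[0])

    @property
    def best_position(self) -> np.ndarray:
        return self.positions[0].copy()

    def update(self, position, energy: float) -> bool:
        """Bubble-sort style update: replace the worst member if beaten.

        The candidate overwrites the tail entry, then bubbles toward the
        head while it is strictly better than its neighbour; pool size is
        invariant.  Returns True if the pool changed.
        """
        if energy >= self.energies[-1]:
            return False
        self.positions[-1] = position
        self.energies[-1] = energy
        i = self.capacity - 1
        while i > 0 and self.energies[i] < self.energies[i - 1]:
            self.energies[i - 1], self.energies[i] = (
                self.energies[i], self.energies[i - 1],
            )
            tmp = self.positions[i - 1].copy()
            self.positions[i - 1] = self.positions[i]
            self.positions[i] = tmp
            i -= 1
        return True


def update_pool(pool: RaindropPool, candidate: Raindrop) -> RaindropPool:
    """Functional wrapper over :meth:`RaindropPool.update`."""
    pool.update(candidate.position, candidate.energy)
    return pool


def gaussian_perturb(c, scale: float, beta: float, space: SearchSpace, rng):
    """Gaussian jitter with per-dimension SD ``scale * beta * (d_i - b_i)``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    c = np.asarray(c, dtype=float)
    sd = scale * beta * space.width
    return space.clip(c + rng.normal(0.0, 1.0, c.shape) * sd)


# -- the optimizer ---------------------------------------------------------


@dataclass(frozen=True)
class OptimizerConfig:
    """Run parameters for :func:`optimize`.

    ``beta0 = 0.005`` is the flow-coefficient optimum for this schedule;
    stagnation and flow limits default to 10 and 3.  ``rank_bias`` shapes
    the pool-member selection during flow steps: a member of rank ``r``
    (0 = best) is drawn with the law ``floor(capacity * U^rank_bias)``, so
    larger values concentrate flow toward the best pool members.
    """

    population: int = 30
    pool_capacity: int = 20
    beta0: float = 0.005
    max_stagnation: int = 10
    max_flow: int = 3
    n_iterations: int = 1000
    perturb_scale: float = 0.1
    rank_bias: float = 4.0
    use_obl: bool = True
    seed: int | None = None

    def validate(self) -> None:
        for name in ("population", "pool_capacity", "max_stagnation",
                     "max_flow", "n_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be > 0")
        if self.perturb_scale <= 0:
            raise ValueError("perturb_scale must be > 0")
        if self.rank_bias < 1:
            raise ValueError("rank_bias must be >= 1")
        if self.pool_capacity > self.population:
            raise ValueError("pool_capacity cannot exceed the population size")


@dataclass
class ConvergenceTrace:
    """Best-so-far fitness per iteration (index 0 = after initialization)."""

    best_fitness: np.ndarray
    best_position: np.ndarray
    n_evaluations: int
    beta_history: np.ndarray = field(default=None, repr=False)
    evaluations_history: np.ndarray = field(default=None, repr=False)

    @property
    def final(self) -> float:
        return float(self.best_fitness[-1])

    def to_csv(self, path) -> None:
        """Write (iteration, best_fitness, evaluations) rows."""
        import pandas as pd

        ev = self.evaluations_history
        if ev is None:
            ev = np.full(self.best_fitness.size, self.n_evaluations)
        pd.DataFrame(
            {
                "iteration": np.arange(self.best_fitness.size),
                "best_fitness": self.best_fitness,
                "evaluations": ev.astype(int),
            }
        ).to_csv(path, index=False)


def _batch_eval(objective, P: np.ndarray) -> np.ndarray:
    """Evaluate objective on rows of P, using a vectorized call when possible."""
    try:
        out = np.asarray(objective(P), dtype=float)
        if out.shape == (P.shape[0],):
            return out
    except Exception:
        pass
    return np.array([float(objective(row)) for row in P])


def optimize(objective, space: SearchSpace, config: OptimizerConfig) -> ConvergenceTrace:
    """Minimize ``objective`` over ``space`` with (OBL+)ARA.

    Per iteration: (1) every raindrop takes a random number (1..max_flow) of
    flow steps toward rank-biased pool members and receives a Gaussian
    perturbation; (2) with ``use_obl`` the candidate is replaced by its
    inverse point when that is strictly fitter; (3) candidates enter the
    pool via the bubble update; (4) a raindrop keeps its candidate only when
    it improves, otherwise its stagnation counter grows, and beyond
    ``max_stagnation`` the drop is restarted — at its inverse point when
    ``use_obl`` restarts are meaningful (always, since the inverse-point
    escape is part of the base flow), with counters reset; (5) the flow
    coefficient decays.  The returned best-so-far trace is non-increasing.
    """
    config.validate()
    if config.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(config.seed)
    pop, cap = config.population, config.pool_capacity
    P = space.sample(rng, pop)
    F = _batch_eval(objective, P)
    evals = pop
    if not np.all(np.isfinite(F)):
        bad = P[~np.isfinite(F)][0]
        raise ValueError(f"objective returned non-finite value at {bad}")
    if config.use_obl:
        P_inv = space.lower + space.upper - P
        F_inv = _batch_eval(objective, P_inv)
        evals += pop
        better = F_inv < F
        P[better] = P_inv[better]
        F[better] = F_inv[better]
    order = np.argsort(F, kind="stable")
    pool = RaindropPool(P[order[:cap]], F[order[:cap]])
    stagnation = np.zeros(pop, dtype=int)
    beta = config.beta0
    T = config.n_iterations
    trace = np.empty(T + 1)
    betas = np.empty(T + 1)
    ev_hist = np.empty(T + 1, dtype=np.int64)
    trace[0] = pool.best_energy
    betas[0] = beta
    ev_hist[0] = evals

    for t in range(1, T + 1):
        # flow steps toward rank-biased pool members
        C = P.copy()
        n_steps = rng.integers(1, config.max_flow + 1, pop)
        for step in range(config.max_flow):
            active = n_steps > step
            ranks = (cap * rng.random(pop) ** config.rank_bias).astype(int)
            ranks = ranks.clip(0, cap - 1)
            frac = rng.random((pop, space.dim))
            targets = pool.positions[ranks]
            move = frac * (targets - C)
            C[active] += move[active]
        C += rng.normal(0.0, 1.0, C.shape) * (config.perturb_scale * beta * space.width)
        C = space.clip(C)
        Fc = _batch_eval(objective, C)
        evals += pop
        if config.use_obl:
            C_inv = space.lower + space.upper - C
            Fci = _batch_eval(objective, C_inv)
            evals += pop
            better = Fci < Fc
            C[better] = C_inv[better]
            Fc[better] = Fci[better]
        for i in range(pop):
            pool.update(C[i], Fc[i])
        improved = Fc < F
        P[improved] = C[improved]
        F[improved] = Fc[improved]
        stagnation[improved] = 0
        stagnation[~improved] += 1
        stuck = stagnation > config.max_stagnation
        if np.any(stuck):
            if config.use_obl:
                P[stuck] = space.lower + space.upper - space.clip(P[stuck])
            else:
                P[stuck] = space.sample(rng, int(stuck.sum()))
            F[stuck] = _batch_eval(objective, P[stuck])
            evals += int(stuck.sum())
            for i in np.where(stuck)[0]:
                pool.update(P[i], F[i])
            stagnation[stuck] = 0
        beta = update_flow_coefficient(FlowState(beta=beta, t=t, T=T)).beta
        trace[t] = pool.best_energy
        betas[t] = beta
        ev_hist[t] = evals

    return ConvergenceTrace(
        best_fitness=trace,
        best_position=pool.best_position,
        n_evaluations=evals,
        beta_history=betas,
        evaluations_history=ev_hist,
    )


# -- baselines -------------------------------------------------------------


def differential_evolution(objective, space, n_iterations, seed=None,
                           population=30, F=0.5, CR=0.9) -> ConvergenceTrace:
    """Classic DE/rand/1/bin under the same tracing conventions."""
    rng = np.random.default_rng(seed)
    pop = population
    P = space.sample(rng, pop)
    fit = _batch_eval(objective, P)
    evals = pop
    trace = np.empty(n_iterations + 1)
    ev_hist = np.empty(n_iterations + 1, dtype=np.int64)
    trace[0] = fit.min()
    ev_hist[0] = evals
    for t in range(1, n_iterations + 1):
        idx = np.arange(pop)
        r1 = rng.integers(0, pop, pop)
        r2 = rng.integers(0, pop, pop)
        r3 = rng.integers(0, pop, pop)
        for name, r in (("r1", r1), ("r2", r2), ("r3", r3)):
            clash = r == idx
            while np.any(clash):
                r[clash] = rng.integers(0, pop, int(clash.sum()))
                clash = r == idx
        V = P[r1] + F * (P[r2] - P[r3])
        cross = rng.random((pop, space.dim)) < CR
        jrand = rng.integers(0, space.dim, pop)
        cross[np.arange(pop), jrand] = True
        U = np.where(cross, V, P)
        U = space.clip(U)
        fu = _batch_eval(objective, U)
        evals += pop
        better = fu <= fit
        P[better] = U[better]
        fit[better] = fu[better]
        trace[t] = min(trace[t - 1], fit.min())
        ev_hist[t] = evals
    best = int(np.argmin(fit))
    return ConvergenceTrace(trace, P[best].copy(), evals,
                            evaluations_history=ev_hist)


def particle_swarm(objective, space, n_iterations, seed=None, population=30,
                   w_start=0.9, w_end=0.4, c1=2.0, c2=2.0) -> ConvergenceTrace:
    """Global-best PSO with linearly decaying inertia weight."""
    rng = np.random.default_rng(seed)
    pop = population
    X = space.sample(rng, pop)
    vmax = 0.5 * space.width
    V = rng.uniform(-1.0, 1.0, (pop, space.dim)) * vmax
    fit = _batch_eval(objective, X)
    evals = pop
    pbest = X.copy()
    pbest_fit = fit.copy()
    g = int(np.argmin(fit))
    gbest = X[g].copy()
    gbest_fit = float(fit[g])
    trace = np.empty(n_iterations + 1)
    ev_hist = np.empty(n_iterations + 1, dtype=np.int64)
    trace[0] = gbest_fit
    ev_hist[0] = evals
    for t in range(1, n_iterations + 1):
        w = w_start + (w_end - w_start) * (t - 1) / max(1, n_iterations - 1)
        V = (w * V
             + c1 * rng.random((pop, space.dim)) * (pbest - X)
             + c2 * rng.random((pop, space.dim)) * (gbest - X))
        V = np.clip(V, -vmax, vmax)
        X = space.clip(X + V)
        fit = _batch_eval(objective, X)
        evals += pop
        better = fit < pbest_fit
        pbest[better] = X[better]
        pbest_fit[better] = fit[better]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest = pbest[g].copy()
        trace[t] = gbest_fit
        ev_hist[t] = evals
    return ConvergenceTrace(trace, gbest, evals,
                            evaluations_history=ev_hist)


# -- comparison harness ----------------------------------------------------

ALGORITHMS = ("obl_ara", "ara", "de", "pso")


def compare_optimizers(objective, space, n_iterations: int = 1000,
                       n_runs: int = 30, seed: int = 0,
                       config: OptimizerConfig | None = None) -> dict:
    """Run OBL+ARA, plain ARA, DE and PSO under equal iteration budgets.

    Every algorithm sees the same per-run seeds (paired comparison).
    Returns, per algorithm, the final fitness of every run, the median
    final fitness, the mean best-so-far trace and the mean evaluation count.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base = config or OptimizerConfig()
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in np.random.SeedSequence(seed).spawn(n_runs)]
    results = {}
    for alg in ALGORITHMS:
        finals, traces, ev = [], [], []
        for s in seeds:
            if alg in ("obl_ara", "ara"):
                cfg = replace(base, use_obl=(alg == "obl_ara"), seed=s,
                              n_iterations=n_iterations)
                tr = optimize(objective, space, cfg)
            elif alg == "de":
                tr = differential_evolution(objective, space, n_iterations, seed=s,
                                            population=base.population)
            else:
                tr = particle_swarm(objective, space, n_iterations, seed=s,
                                    population=base.population)
            finals.append(tr.final)
            traces.append(tr.best_fitness)
            ev.append(tr.n_evaluations)
        results[alg] = {
            "final": np.asarray(finals),
            "median_final": float(np.median(finals)),
            "mean_trace": np.mean(traces, axis=0),
            "mean_evaluations": float(np.mean(ev)),
        }
    return results
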