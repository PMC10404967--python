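"""Population metaheuristics: Harris Hawks optimization, differential
evolution with a self-adaptive (pliable) scaling factor, their nested hybrid,
grey wolf optimization and grasshopper optimization.

All optimizers minimize, clip candidates to the declared box after every
update, and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "HHOConfig",
    "SFPDEConfig",
    "SwarmConfig",
    "HybridConfig",
    "OptimResult",
    "escape_energy",
    "closeness_parameter",
    "adaptive_scale",
    "binarize",
    "hho",
    "sfpde",
    "hho_sfpde",
    "gwo",
    "goa",
    "sphere",
    "rastrigin",
]


# ---------------------------------------------------------------------------
# Problem description


@dataclasses.dataclass
class ObjectiveSpec:
    """A box-constrained minimization problem.

    `fitness` maps a candidate vector (or a bit vector in binary mode) to a
    finite float. `constraint`, when given, returns a violation magnitude
    >= 0 that is added to the fitness scaled by `penalty_weight`.
    """

    dimension: int
    lower: np.ndarray | float
    upper: np.ndarray | float
    fitness: Callable[[np.ndarray], float]
    constraint: Callable[[np.ndarray], float] | None = None
    penalty_weight: float = 1e6

    def __post_init__(self) -> None:
        self.lower = np.broadcast_to(
            np.asarray(self.lower, float), (self.dimension,)
        ).copy()
        self.upper = np.broadcast_to(
            np.asarray(self.upper, float), (self.dimension,)
        ).copy()
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    def evaluate(self, x: np.ndarray) -> float:
        value = float(self.fitness(x))
        if not math.isfinite(value):
            raise ValueError(f"fitness returned non-finite value for {x!r}")
        if self.constraint is not None:
            violation = float(self.constraint(x))
            if violation > 0:
                value += self.penalty_weight * violation
        return value

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclasses.dataclass
class HHOConfig:
    pop_size: int = 50
    max_iters: int = 500
    levy_beta: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (0.5 <= self.levy_beta <= 1.5):
            raise ValueError("levy_beta must lie in [0.5, 1.5]")


@dataclasses.dataclass
class SFPDEConfig:
    pop_size: int = 100
    max_iters: int = 1000
    crossover_rate: float = 0.7
    binary: bool = False
    stop_tol: float | None = None  # generation-error (mean-fitness) threshold
    record_history: bool = False  # keep per-generation population fitness
    scale_modulation: float = 1.0  # multiplier on the adaptive scale (hybrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (three distinct partners)")
        if not (0 < self.crossover_rate < 1):
            raise ValueError("crossover_rate must lie in (0, 1)")


@dataclasses.dataclass
class SwarmConfig:
    """Shared config for the GWO and GOA swarms."""

    pop_size: int = 50
    max_iters: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")


@dataclasses.dataclass
class HybridConfig:
    outer: HHOConfig = dataclasses.field(
        default_factory=lambda: HHOConfig(pop_size=50, max_iters=500)
    )
    inner: SFPDEConfig = dataclasses.field(
        default_factory=lambda: SFPDEConfig(
            pop_size=75, max_iters=500, stop_tol=1e-8
        )
    )
    cr_bounds: tuple[float, float] = (0.1, 0.95)
    modulation_bounds: tuple[float, float] = (0.5, 1.5)
    outer_stop_tol: float = 1e-8
    seed: int = 0


@dataclasses.dataclass
class OptimResult:
    best_candidate: np.ndarray
    best_fitness: float
    convergence_trace: np.ndarray  # best-so-far per iteration
    iterations_run: int
    extras: dict = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# Scalar helpers


def escape_energy(E0: float, t: int, T: int) -> float:
    """Prey escape energy 2*E0*(1 - t/T), decaying linearly over iterations."""
    if T == 0:
        raise ZeroDivisionError("T must be positive")
    if not (0 <= t <= T):
        raise ValueError("t must lie in [0, T]")
    if not (-1 <= E0 <= 1):
        raise ValueError("E0 must lie in [-1, 1]")
    return 2.0 * E0 * (1.0 - t / T)


def closeness_parameter(fit_q: float, fit_best: float, fit_worst: float) -> float:
    """Normalized position of a fitness value between population worst (0)
    and best (1). All-equal population maps to 1 (fully converged)."""
    if fit_best == fit_worst:
        return 1.0
    cp = (fit_q - fit_worst) / (fit_best - fit_worst)
    return float(np.clip(cp, 0.0, 1.0))


def adaptive_scale(cp: float) -> float:
    """Pliable DE scaling factor S = 1/(1 + tanh(2 CP)); image is (0.5, 1]."""
    if not (0 <= cp <= 1):
        raise ValueError("CP must lie in [0, 1]")
    return 1.0 / (1.0 + math.tanh(2.0 * cp))


def binarize(candidate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic sigmoid thresholding of a real vector to bits."""
    x = np.asarray(candidate, float)
    with np.errstate(over="ignore"):
        probs = 1.0 / (1.0 + np.exp(-x))
    return (rng.random(x.shape) < probs).astype(int)


def _levy_flight(rng: np.random.Generator, dim: int, beta: float) -> np.ndarray:
    """Mantegna-style Levy step of the given dimension."""
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    g = rng.standard_normal(dim) * sigma
    h = rng.standard_normal(dim)
    return 0.01 * g / np.abs(h) ** (1 / beta)


# ---------------------------------------------------------------------------
# Harris Hawks optimization


def hho(objective: ObjectiveSpec, config: HHOConfig) -> OptimResult:
    """Harris Hawks minimization.

    Exploration while |E| >= 1 (two random strategies); four exploitation
    branches keyed on (r, |E|): soft besiege, hard besiege, and their
    rapid-dive variants with greedy Levy-flight acceptance.
    """
    rng = np.random.default_rng(config.seed)
    dim = objective.dimension
    lb, ub = objective.lower, objective.upper
    pop = lb + rng.random((config.pop_size, dim)) * (ub - lb)
    fits = np.array([objective.evaluate(x) for x in pop])
    best_idx = int(np.argmin(fits))
    prey = pop[best_idx].copy()
    prey_fit = float(fits[best_idx])
    trace = np.empty(config.max_iters)

    for t in range(config.max_iters):
        mean_pos = pop.mean(axis=0)
        for i in range(config.pop_size):
            E0 = rng.uniform(-1, 1)
            E = escape_energy(E0, t, config.max_iters)
            if abs(E) >= 1:  # exploration
                if rng.random() >= 0.5:
                    other = pop[rng.integers(config.pop_size)]
                    r1, r2 = rng.random(2)
                    new = other - r1 * np.abs(other - 2 * r2 * pop[i])
                else:
                    r3, r4 = rng.random(2)
                    new = (prey - mean_pos) - r3 * (lb + r4 * (ub - lb))
            else:  # exploitation
                r = rng.random()
                J = 2 * (1 - rng.random())  # jump strength in [0, 2]
                delta = prey - pop[i]
                if r >= 0.5 and abs(E) >= 0.5:  # soft besiege
                    new = delta - E * np.abs(J * prey - pop[i])
                elif r >= 0.5:  # hard besiege
                    new = prey - E * np.abs(delta)
                else:
                    anchor = pop[i] if abs(E) >= 0.5 else mean_pos
                    A = prey - E * np.abs(J * prey - anchor)
                    A = objective.clip(A)
                    fA = objective.evaluate(A)
                    if fA < fits[i]:
                        new = A
                    else:
                        B = A + rng.random(dim) * _levy_flight(
                            rng, dim, config.levy_beta
                        )
                        B = objective.clip(B)
                        fB = objective.evaluate(B)
                        new = B if fB < fits[i] else pop[i]
            new = objective.clip(new)
            f_new = objective.evaluate(new)
            pop[i] = new
            fits[i] = f_new
            if f_new < prey_fit:
                prey_fit = f_new
                prey = new.copy()
        trace[t] = prey_fit
    return OptimResult(prey, prey_fit, trace, config.max_iters)


# ---------------------------------------------------------------------------
# Pliable differential evolution


def sfpde(objective: ObjectiveSpec, config: SFPDEConfig) -> OptimResult:
    """DE/current/1 with a per-individual adaptive scaling factor.

    Each individual q gets a closeness parameter CP in [0, 1] from its fitness
    position between the population's worst and best, a scaling factor
    S_q = 1/(1 + tanh(2 CP)), a mutant X_q + S_q (X_q1 - X_q2), binomial
    crossover with a forced component, and greedy survivor selection. In
    binary mode candidates are sigmoid-thresholded to bit masks before
    fitness evaluation.
    """
    rng = np.random.default_rng(config.seed)
    dim = objective.dimension
    np_ = config.pop_size
    lb, ub = objective.lower, objective.upper

    pop = lb + rng.random((np_, dim)) * (ub - lb)

    def fitness_of(x: np.ndarray) -> tuple[float, np.ndarray | None]:
        if config.binary:
            bits = binarize(x, rng)
            return objective.evaluate(bits), bits
        return objective.evaluate(x), None

    evals = [fitness_of(x) for x in pop]
    fits = np.array([e[0] for e in evals])
    masks = [e[1] for e in evals]
    best_idx = int(np.argmin(fits))
    best = pop[best_idx].copy()
    best_fit = float(fits[best_idx])
    best_mask = None if masks[best_idx] is None else masks[best_idx].copy()

    trace = []
    iters_run = 0
    prev_mean: float | None = None
    scales_seen: list[float] = []
    history: list[np.ndarray] = [fits.copy()] if config.record_history else []
    for _ in range(config.max_iters):
        iters_run += 1
        f_best = fits.min()
        f_worst = fits.max()
        for q in range(np_):
            cp = closeness_parameter(fits[q], f_best, f_worst)
            s_q = adaptive_scale(cp) * config.scale_modulation
            scales_seen.append(adaptive_scale(cp))
            partners = rng.choice(
                [j for j in range(np_) if j != q], size=2, replace=False
            )
            mutant = pop[q] + s_q * (pop[partners[0]] - pop[partners[1]])
            mutant = objective.clip(mutant)
            i_rand = rng.integers(dim)
            cross = rng.random(dim) <= config.crossover_rate
            cross[i_rand] = True
            trial = np.where(cross, mutant, pop[q])
            f_trial, m_trial = fitness_of(trial)
            if f_trial <= fits[q]:  # greedy: never deteriorates
                pop[q] = trial
                fits[q] = f_trial
                masks[q] = m_trial
                if f_trial < best_fit:
                    best_fit = float(f_trial)
                    best = trial.copy()
                    best_mask = None if m_trial is None else m_trial.copy()
        if config.record_history:
            history.append(fits.copy())
        trace.append(best_fit)
        # generation error = change of the population's mean fitness
        gen_mean = float(fits.mean())
        if (
            config.stop_tol is not None
            and prev_mean is not None
            and abs(prev_mean - gen_mean) < config.stop_tol
        ):
            break
        prev_mean = gen_mean
    extras = {"adaptive_scales": np.array(scales_seen)}
    if config.record_history:
        extras["fitness_history"] = np.array(history)
    if config.binary:
        extras["best_mask"] = best_mask
    return OptimResult(best, best_fit, np.array(trace), iters_run, extras)


def hho_sfpde(objective: ObjectiveSpec, config: HybridConfig) -> OptimResult:
    """Nested tuner: an outer HHO searches the SFPDE control parameters
    (crossover rate, scale modulation); each hawk's fitness is the best value
    reached by an inner SFPDE run under those controls. Returns the overall
    best inner solution."""
    rng = np.random.default_rng(config.seed)
    best_inner: OptimResult | None = None

    def hawk_fitness(params: np.ndarray) -> float:
        nonlocal best_inner
        cr = float(np.clip(params[0], *config.cr_bounds))
        mod = float(np.clip(params[1], *config.modulation_bounds))
        inner_cfg = dataclasses.replace(
            config.inner,
            crossover_rate=cr,
            scale_modulation=mod,
            seed=int(rng.integers(2**31 - 1)),
        )
        result = sfpde(objective, inner_cfg)
        if best_inner is None or result.best_fitness < best_inner.best_fitness:
            best_inner = result
            best_inner.extras["tuned_cr"] = cr
            best_inner.extras["tuned_modulation"] = mod
        return result.best_fitness

    outer_obj = ObjectiveSpec(
        dimension=2,
        lower=np.array([config.cr_bounds[0], config.modulation_bounds[0]]),
        upper=np.array([config.cr_bounds[1], config.modulation_bounds[1]]),
        fitness=hawk_fitness,
    )
    outer_cfg = dataclasses.replace(config.outer, seed=config.seed)
    outer = hho(outer_obj, outer_cfg)
    assert best_inner is not None
    best_inner.extras["outer_trace"] = outer.convergence_trace
    return best_inner


# ---------------------------------------------------------------------------
# Grey wolf optimization


def gwo(objective: ObjectiveSpec, config: SwarmConfig) -> OptimResult:
    """Grey wolf minimization: every wolf moves to the mean of three
    leader-guided positions, with the exploration coefficient decaying 2 -> 0."""
    if config.pop_size < 3:
        raise ValueError("gwo needs at least 3 wolves")
    rng = np.random.default_rng(config.seed)
    dim = objective.dimension
    lb, ub = objective.lower, objective.upper
    pop = lb + rng.random((config.pop_size, dim)) * (ub - lb)
    fits = np.array([objective.evaluate(x) for x in pop])
    trace = np.empty(config.max_iters)
    best = pop[np.argmin(fits)].copy()
    best_fit = float(fits.min())

    for t in range(config.max_iters):
        order = np.argsort(fits, kind="stable")
        leaders = pop[order[:3]].copy()  # alpha, beta, gamma
        a = 2.0 * (1 - t / config.max_iters)
        for i in range(config.pop_size):
            moves = np.empty((3, dim))
            for j in range(3):
                r1 = rng.random(dim)
                r2 = rng.random(dim)
                K = 2 * a * r1 - a
                H = 2 * r2
                U = np.abs(H * leaders[j] - pop[i])
                moves[j] = leaders[j] - K * U
            new = objective.clip(moves.mean(axis=0))
            pop[i] = new
            fits[i] = objective.evaluate(new)
            if fits[i] < best_fit:
                best_fit = float(fits[i])
                best = new.copy()
        trace[t] = best_fit
    return OptimResult(best, best_fit, trace, config.max_iters)


# ---------------------------------------------------------------------------
# Grasshopper optimization


def _social_force(r: np.ndarray, f: float = 0.5, l_att: float = 1.5) -> np.ndarray:
    return f * np.exp(-r / l_att) - np.exp(-r)


def goa(objective: ObjectiveSpec, config: SwarmConfig) -> OptimResult:
    """Grasshopper minimization: comfort coefficient decays linearly 1 -> 1e-5,
    positions aggregate pairwise social forces around the best-so-far target."""
    rng = np.random.default_rng(config.seed)
    dim = objective.dimension
    lb, ub = objective.lower, objective.upper
    n = config.pop_size
    pop = lb + rng.random((n, dim)) * (ub - lb)
    fits = np.array([objective.evaluate(x) for x in pop])
    best_idx = int(np.argmin(fits))
    target = pop[best_idx].copy()
    best_fit = float(fits[best_idx])
    trace = np.empty(config.max_iters)
    c_max, c_min = 1.0, 1e-5

    for t in range(config.max_iters):
        c = c_max - t * (c_max - c_min) / config.max_iters
        new_pop = np.empty_like(pop)
        for i in range(n):
            diff = pop - pop[i]  # (n, dim)
            dist = np.linalg.norm(diff, axis=1)
            live = dist > 0  # coincident agents exert no force
            if np.any(live):
                d = dist[live][:, None]
                r_dim = 2.0 + d % 2.0  # map distances into [2, 4)
                forces = (
                    c
                    * (ub - lb)
                    / 2.0
                    * _social_force(np.abs(diff[live]) / d * r_dim)
                    * diff[live]
                    / d
                )
                social = forces.sum(axis=0)
            else:
                social = np.zeros(dim)
            new_pop[i] = objective.clip(c * social + target)
        pop = new_pop
        fits = np.array([objective.evaluate(x) for x in pop])
        idx = int(np.argmin(fits))
        if fits[idx] < best_fit:
            best_fit = float(fits[idx])
            target = pop[idx].copy()
        trace[t] = best_fit
    return OptimResult(target, best_fit, trace, config.max_iters)


# ---------------------------------------------------------------------------
# Benchmark objectives


def sphere(dim: int, bound: float = 10.0) -> ObjectiveSpec:
    return ObjectiveSpec(dim, -bound, bound, lambda x: float(np.sum(x**2)))


def rastrigin(dim: int, bound: float = 5.12) -> ObjectiveSpec:
    def f(x: np.ndarray) -> float:
        return float(10 * x.size + np.sum(x**2 - 10 * np.cos(2 * np.pi * x)))

    return ObjectiveSpec(dim, -bound, bound, f)
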