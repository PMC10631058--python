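"""Real-coded genetic algorithm and particle swarm minimizers.

Both are written from scratch (they are part of the method under study,
not infrastructure). Defaults follow the reported budgets: GA runs 500
iterations with population 100 and crossover fraction 0.5; PSO runs 100
iterations with 200 particles, inertia 1 and cognitive acceleration 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .metrics import CVReport
from .svm import DEFAULT_C, DEFAULT_EPSILON, KernelSpec, evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "SearchSpace",
    "GAConfig",
    "PSOConfig",
    "OptimizationResult",
    "ga_minimize",
    "pso_minimize",
    "tune_svm",
    "TuneResult",
]


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds per parameter; log-scaled dimensions are searched in log10."""

    bounds: tuple[tuple[float, float], ...]
    scales: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        scales = self.scales or tuple("linear" for _ in self.bounds)
        if len(scales) != len(self.bounds):
            raise ConfigurationError("one scale per bound required")
        for (lo, hi), scale in zip(self.bounds, scales):
            if not hi > lo:
                raise ConfigurationError(f"invalid bounds ({lo}, {hi})")
            if scale not in {"linear", "log"}:
                raise ConfigurationError(f"unknown scale {scale!r}")
            if scale == "log" and lo <= 0:
                raise ConfigurationError("log scale requires positive bounds")
        object.__setattr__(self, "scales", scales)

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def _internal_bounds(self) -> np.ndarray:
        out = []
        for (lo, hi), scale in zip(self.bounds, self.scales):
            out.append((np.log10(lo), np.log10(hi)) if scale == "log" else (lo, hi))
        return np.asarray(out)

    def to_external(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        x = z.copy()
        for d, scale in enumerate(self.scales):
            if scale == "log":
                x[..., d] = 10.0 ** z[..., d]
        return x

    def to_internal(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        z = x.copy()
        for d, scale in enumerate(self.scales):
            if scale == "log":
                z[..., d] = np.log10(x[..., d])
        return z


@dataclass(frozen=True)
class GAConfig:
    max_iterations: int = 500
    population_size: int = 100
    crossover_fraction: float = 0.5
    mutation_rate: float = 0.1
    mutation_sigma: float = 0.1  # fraction of each dimension's range
    elitism: int = 1
    blx_alpha: float = 0.5
    tournament_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ConfigurationError("crossover_fraction must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ConfigurationError("elitism must be in [0, population_size)")


@dataclass(frozen=True)
class PSOConfig:
    max_iterations: int = 100
    population_size: int = 200
    inertia_weight: float = 1.0
    cognitive_acceleration: float = 1.0
    social_acceleration: float = 1.0
    velocity_clamp: float = 0.2  # fraction of each dimension's range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.inertia_weight < 0:
            raise ConfigurationError("inertia_weight must be >= 0")


@dataclass
class OptimizationResult:
    best_x: np.ndarray
    best_value: float
    trace: list[float]  # best-so-far after init and after each iteration
    n_evaluations: int

    def __post_init__(self) -> None:
        trace = np.asarray(self.trace)
        if (np.diff(trace) > 1e-12).any():
            raise ConfigurationError("best-so-far trace must be non-increasing")


def _evaluate_population(objective, space: SearchSpace, Z: np.ndarray) -> np.ndarray:
    """Objective values per row; non-finite results are penalized with +inf."""
    values = np.empty(len(Z))
    X = space.to_external(Z)
    for i, x in enumerate(X):
        v = objective(x if space.dim > 1 else float(x[0]))
        if not np.isfinite(v):
            logger.warning("non-finite objective at %s; discarding candidate", x)
            v = np.inf
        values[i] = v
    return values


def _init_population(space: SearchSpace, pop: int, rng: np.random.Generator,
                     initial_points: Sequence | None) -> np.ndarray:
    lo, hi = space._internal_bounds().T
    Z = rng.uniform(lo, hi, size=(pop, space.dim))
    if initial_points is not None:
        pts = np.atleast_2d(np.asarray(initial_points, dtype=float))
        k = min(len(pts), pop)
        Z[:k] = np.clip(space.to_internal(pts[:k]), lo, hi)
    return Z


def ga_minimize(objective: Callable, space: SearchSpace,
                config: GAConfig | None = None,
                initial_points: Sequence | None = None) -> OptimizationResult:
    """Real-coded GA: tournament selection, BLX-alpha crossover on a
    fraction of the population, Gaussian mutation, elitism."""
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = space._internal_bounds().T
    span = hi - lo

    Z = _init_population(space, config.population_size, rng, initial_points)
    values = _evaluate_population(objective, space, Z)
    n_evals = len(Z)
    order = np.argsort(values, kind="stable")
    Z, values = Z[order], values[order]
    best_z, best_v = Z[0].copy(), float(values[0])
    trace = [best_v]

    def tournament() -> int:
        contenders = rng.integers(0, config.population_size, size=config.tournament_size)
        return int(contenders[np.argmin(values[contenders])])

    n_cross = int(round(config.crossover_fraction * config.population_size))
    for _ in range(config.max_iterations):
        children = np.empty_like(Z)
        children[: config.elitism] = Z[: config.elitism]
        pos = config.elitism
        # crossover offspring
        produced = 0
        while produced < n_cross and pos < config.population_size:
            p1, p2 = Z[tournament()], Z[tournament()]
            low = np.minimum(p1, p2) - config.blx_alpha * np.abs(p1 - p2)
            high = np.maximum(p1, p2) + config.blx_alpha * np.abs(p1 - p2)
            children[pos] = rng.uniform(low, high)
            pos += 1
            produced += 1
        # remainder: selected copies
        while pos < config.population_size:
            children[pos] = Z[tournament()]
            pos += 1
        # Gaussian mutation on non-elites
        if config.mutation_rate > 0 and config.mutation_sigma > 0:
            mutable = children[config.elitism:]
            hit = rng.random(mutable.shape) < config.mutation_rate
            noise = rng.normal(0.0, config.mutation_sigma * span, size=mutable.shape)
            children[config.elitism:] = mutable + hit * noise
        children = np.clip(children, lo, hi)

        values_new = _evaluate_population(objective, space, children)
        n_evals += len(children)
        order = np.argsort(values_new, kind="stable")
        Z, values = children[order], values_new[order]
        if float(values[0]) < best_v:
            best_z, best_v = Z[0].copy(), float(values[0])
        trace.append(best_v)

    return OptimizationResult(space.to_external(best_z), best_v, trace, n_evals)


def pso_minimize(objective: Callable, space: SearchSpace,
                 config: PSOConfig | None = None,
                 initial_points: Sequence | None = None) -> OptimizationResult:
    """Canonical PSO: inertia plus cognitive/social pulls, velocity and
    position clamped to the search box."""
    config = config or PSOConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = space._internal_bounds().T
    span = hi - lo
    vmax = config.velocity_clamp * span

    Z = _init_population(space, config.population_size, rng, initial_points)
    V = np.zeros_like(Z)
    values = _evaluate_population(objective, space, Z)
    n_evals = len(Z)

    pbest_z, pbest_v = Z.copy(), values.copy()
    g = int(np.argmin(values))
    gbest_z, gbest_v = Z[g].copy(), float(values[g])
    trace = [gbest_v]

    for _ in range(config.max_iterations):
        r1 = rng.random(Z.shape)
        r2 = rng.random(Z.shape)
        V = (config.inertia_weight * V
             + config.cognitive_acceleration * r1 * (pbest_z - Z)
             + config.social_acceleration * r2 * (gbest_z - Z))
        V = np.clip(V, -vmax, vmax)
        Z = np.clip(Z + V, lo, hi)

        values = _evaluate_population(objective, space, Z)
        n_evals += len(Z)
        improved = values < pbest_v
        pbest_z[improved] = Z[improved]
        pbest_v[improved] = values[improved]
        g = int(np.argmin(pbest_v))
        if pbest_v[g] < gbest_v:
            gbest_v = float(pbest_v[g])
            gbest_z = pbest_z[g].copy()
        trace.append(gbest_v)

    return OptimizationResult(space.to_external(gbest_z), gbest_v, trace, n_evals)


# --------------------------------------------------------------------------
# SVM kernel-parameter tuning

GAMMA_SPACE = SearchSpace(((1e-4, 1e2),), ("log",))
C_SPACE = SearchSpace(((1e-3, 1e3),), ("log",))


@dataclass
class TuneResult:
    report: CVReport
    optimization: OptimizationResult
    tuned_parameter: str
    best_value: float


def tune_svm(features, targets, kernel: KernelSpec, folds,
             optimizer: str = "ga", config: GAConfig | PSOConfig | None = None,
             space: SearchSpace | None = None, C: float = DEFAULT_C,
             epsilon: float = DEFAULT_EPSILON, metadata: dict | None = None) -> TuneResult:
    """Tune the SVM kernel parameter by minimizing pooled CV MSE.

    The tuned parameter is gamma, except for the linear kernel (which has
    none) where the regularization constant C is tuned instead. The
    default parameter is seeded into the initial population, so tuning
    never does worse than the untuned model on the tuning objective.
    ``optimizer='none'`` evaluates the default parameter only.
    """
    X = np.asarray(features, dtype=float)
    tuned = "C" if kernel.kind == "linear" else "gamma"
    default = C if tuned == "C" else 1.0 / X.shape[1]
    if space is None:
        space = C_SPACE if tuned == "C" else GAMMA_SPACE
    default = float(np.clip(default, space.bounds[0][0], space.bounds[0][1]))

    cache: dict[float, float] = {}

    def objective(param: float) -> float:
        key = float(f"{param:.6g}")
        if key not in cache:
            kwargs = {"C": key} if tuned == "C" else {"C": C}
            spec = kernel if tuned == "C" else kernel.with_gamma(key)
            cache[key] = evaluate(X, targets, spec, folds, epsilon=epsilon, **kwargs).mse
        return cache[key]

    if optimizer == "none":
        value = objective(default)
        result = OptimizationResult(np.asarray([default]), value, [value], 1)
        best = default
    elif optimizer == "ga":
        result = ga_minimize(objective, space, config if isinstance(config, GAConfig) else config or GAConfig(),
                             initial_points=[[default]])
        best = float(result.best_x[0])
    elif optimizer == "pso":
        result = pso_minimize(objective, space, config if isinstance(config, PSOConfig) else config or PSOConfig(),
                              initial_points=[[default]])
        best = float(result.best_x[0])
    else:
        raise ConfigurationError(f"unknown optimizer {optimizer!r}; choose ga, pso or none")

    meta = dict(metadata or {})
    meta.update({"optimizer": optimizer, "tuned_parameter": tuned, "best_param": best,
                 "n_objective_evaluations": result.n_evaluations,
                 "cache_size": len(cache)})
    if tuned == "C":
        report = evaluate(X, targets, kernel, folds, C=best, epsilon=epsilon, metadata=meta)
    else:
        report = evaluate(X, targets, kernel.with_gamma(best), folds, C=C,
                          epsilon=epsilon, metadata=meta)
    return TuneResult(report, result, tuned, best)
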