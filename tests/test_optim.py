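import numpy as np
import pytest

from phytostress.exceptions import ConfigurationError
from phytostress.metrics import make_folds
from phytostress.optim import (
    GAConfig,
    PSOConfig,
    SearchSpace,
    ga_minimize,
    pso_minimize,
    tune_svm,
)
from phytostress.svm import KernelSpec

QUAD_SPACE = SearchSpace(((0.0, 10.0),))


def quadratic(x):
    return (x - 2.0) ** 2


def two_basin(x):
    # local minimum near 1 (depth 0.5), global near 7 (depth 1.0);
    # a dense grid search is the oracle for the basin structure
    return -1.0 * np.exp(-((x - 7.0) ** 2) / 0.5) - 0.5 * np.exp(-((x - 1.0) ** 2) / 0.5)


GRID = np.linspace(0.0, 10.0, 20001)
GLOBAL_MIN_X = GRID[np.argmin(two_basin(GRID))]


class TestSearchSpace:
    def test_log_scale_round_trip(self):
        space = SearchSpace(((1e-4, 1e2),), ("log",))
        x = np.array([0.5])
        np.testing.assert_allclose(space.to_external(space.to_internal(x)), x)

    def test_invalid_spaces(self):
        with pytest.raises(ConfigurationError):
            SearchSpace(((1.0, 1.0),))
        with pytest.raises(ConfigurationError):
            SearchSpace(((-1.0, 1.0),), ("log",))


class TestDefaults:
    def test_ga_reported_defaults(self):
        config = GAConfig()
        assert config.max_iterations == 500
        assert config.population_size == 100
        assert config.crossover_fraction == 0.5

    def test_pso_reported_defaults(self):
        config = PSOConfig()
        assert config.max_iterations == 100
        assert config.population_size == 200
        assert config.inertia_weight == 1.0
        assert config.cognitive_acceleration == 1.0


@pytest.mark.parametrize("minimize,config", [
    (ga_minimize, GAConfig(max_iterations=50, population_size=30, seed=0)),
    (pso_minimize, PSOConfig(max_iterations=50, population_size=30, seed=0)),
])
class TestMinimizers:
    def test_quadratic_recovery(self, minimize, config):
        result = minimize(quadratic, QUAD_SPACE, config)
        assert abs(result.best_x[0] - 2.0) < 1e-2

    def test_trace_monotone_and_consistent(self, minimize, config):
        result = minimize(quadratic, QUAD_SPACE, config)
        trace = np.asarray(result.trace)
        assert (np.diff(trace) <= 1e-15).all()
        assert result.best_value == pytest.approx(trace.min())
        assert len(trace) == config.max_iterations + 1

    def test_bounds_respected(self, minimize, config):
        seen = []

        def spy(x):
            seen.append(x)
            return quadratic(x)

        minimize(spy, QUAD_SPACE, config)
        seen = np.asarray(seen)
        assert seen.min() >= 0.0 and seen.max() <= 10.0

    def test_budget_accounting(self, minimize, config):
        result = minimize(quadratic, QUAD_SPACE, config)
        assert result.n_evaluations <= config.population_size * (config.max_iterations + 1)

    def test_determinism(self, minimize, config):
        a = minimize(two_basin, QUAD_SPACE, config)
        b = minimize(two_basin, QUAD_SPACE, config)
        assert a.best_value == b.best_value
        assert a.trace == b.trace

    def test_nonfinite_objective_penalized(self, minimize, config):
        def spiky(x):
            return np.nan if 4.0 < x < 6.0 else quadratic(x)

        result = minimize(spiky, QUAD_SPACE, config)
        assert np.isfinite(result.best_value)


class TestBasinRecovery:
    def test_grid_oracle_confirms_global_basin(self):
        assert abs(GLOBAL_MIN_X - 7.0) < 0.1

    def test_ga_finds_global_basin(self):
        hits = sum(
            abs(ga_minimize(two_basin, QUAD_SPACE,
                            GAConfig(max_iterations=30, population_size=20, seed=s)
                            ).best_x[0] - GLOBAL_MIN_X) < 1.0
            for s in range(100))
        assert hits >= 95

    def test_pso_finds_global_basin(self):
        hits = sum(
            abs(pso_minimize(two_basin, QUAD_SPACE,
                             PSOConfig(max_iterations=30, population_size=20, seed=s)
                             ).best_x[0] - GLOBAL_MIN_X) < 1.0
            for s in range(100))
        assert hits >= 95


class TestDegenerateDynamics:
    def test_both_optimizers_return_best_initial(self):
        initial = [[1.0], [3.0], [2.5], [8.0]]
        ga = ga_minimize(quadratic, QUAD_SPACE,
                         GAConfig(max_iterations=5, population_size=4,
                                  crossover_fraction=0.0, mutation_rate=0.0, seed=0),
                         initial_points=initial)
        pso = pso_minimize(quadratic, QUAD_SPACE,
                           PSOConfig(max_iterations=5, population_size=4,
                                     velocity_clamp=0.0, seed=0),
                           initial_points=initial)
        assert ga.best_x[0] == pytest.approx(2.5)
        assert pso.best_x[0] == pytest.approx(2.5)


def _tiny_problem(seed=0, n=40):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = X[:, 0] - 0.5 * X[:, 1] + rng.normal(scale=0.1, size=n)
    return X, y


SMALL_GA = GAConfig(max_iterations=4, population_size=8, seed=0)
SMALL_PSO = PSOConfig(max_iterations=4, population_size=8, seed=0)


class TestTuneSvm:
    @pytest.mark.parametrize("optimizer,config", [("ga", SMALL_GA), ("pso", SMALL_PSO)])
    def test_tuned_never_worse_than_default(self, optimizer, config):
        for seed in range(3):
            X, y = _tiny_problem(seed)
            folds = make_folds(len(X), seed=seed)
            kernel = KernelSpec("gaussian")
            untuned = tune_svm(X, y, kernel, folds, optimizer="none")
            tuned = tune_svm(X, y, kernel, folds, optimizer=optimizer, config=config)
            assert tuned.report.mse <= untuned.report.mse + 1e-12

    def test_linear_kernel_tunes_C(self):
        X, y = _tiny_problem()
        folds = make_folds(len(X), seed=0)
        result = tune_svm(X, y, KernelSpec("linear"), folds, optimizer="ga", config=SMALL_GA)
        assert result.tuned_parameter == "C"

    def test_one_feature_noiseless_signal(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 3, size=(50, 1))
        y = X[:, 0].copy()
        folds = make_folds(50, seed=5)
        result = tune_svm(X, y, KernelSpec("linear"), folds, optimizer="ga", config=SMALL_GA)
        assert result.report.r2 > 0.99

    def test_determinism(self):
        X, y = _tiny_problem()
        folds = make_folds(len(X), seed=0)
        a = tune_svm(X, y, KernelSpec("gaussian"), folds, optimizer="pso", config=SMALL_PSO)
        b = tune_svm(X, y, KernelSpec("gaussian"), folds, optimizer="pso", config=SMALL_PSO)
        assert a.best_value == b.best_value
        assert a.report.mse == b.report.mse

    def test_objective_cache_reduces_refits(self):
        X, y = _tiny_problem()
        folds = make_folds(len(X), seed=0)
        result = tune_svm(X, y, KernelSpec("gaussian"), folds, optimizer="ga",
                          config=SMALL_GA)
        meta = result.report.metadata
        assert meta["cache_size"] <= meta["n_objective_evaluations"]

    def test_unknown_optimizer(self):
        X, y = _tiny_problem()
        with pytest.raises(ConfigurationError):
            tune_svm(X, y, KernelSpec("gaussian"), make_folds(len(X), seed=0),
                     optimizer="annealing")
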