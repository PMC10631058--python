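"""Orchestration: experiment grid, importance runs, and the ablation.

The grid reproduces the reporting structure of the study design:
feature groups x stress scenarios x kernels x (plain / GA-tuned /
PSO-tuned SVM), each cell scored by 5-fold CV MSE and R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .banzhaf import BanzhafResult, banzhaf_exact, banzhaf_monte_carlo, performance_characteristic
from .data import FEATURE_GROUPS, FeatureTable, load_feature_table
from .exceptions import ConfigurationError
from .metrics import CVReport, make_folds
from .optim import GAConfig, PSOConfig, tune_svm
from .svm import SCENARIOS, KernelSpec, evaluate, scenario_target

logger = logging.getLogger(__name__)

__all__ = [
    "load_dataset",
    "ExperimentGrid",
    "run_grid",
    "run_importance",
    "run_ablation",
    "GRID_COLUMNS",
]

KERNELS = ("linear", "polynomial", "gaussian", "sigmoid")
MODELS = ("svm", "svm-ga", "svm-pso")

GRID_COLUMNS = ["group", "scenario", "kernel", "model", "mse", "r2", "n",
                "best_param", "tuned_parameter", "seed", "status"]


def load_dataset(path, fmt: str | None = None) -> FeatureTable:
    """Load a CSV/XLSX feature file (raw-sheet layout) into a FeatureTable."""
    return load_feature_table(path, fmt)


@dataclass(frozen=True)
class ExperimentGrid:
    """Which cells to run and with what budgets/seed."""

    groups: tuple[str, ...] = ("morphological", "physiological", "mirna")
    scenarios: tuple[str, ...] = SCENARIOS
    kernels: tuple[str, ...] = KERNELS
    models: tuple[str, ...] = MODELS
    seed: int = 0
    k_folds: int = 5
    ga: GAConfig = field(default_factory=GAConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)

    def __post_init__(self) -> None:
        bad = [g for g in self.groups if g not in FEATURE_GROUPS]
        if bad:
            raise ConfigurationError(f"unknown feature group(s) {bad}")
        bad = [s for s in self.scenarios if s not in SCENARIOS]
        if bad:
            raise ConfigurationError(f"unknown scenario(s) {bad}")

    def cells(self):
        idx = 0
        for group in self.groups:
            for scenario in self.scenarios:
                for kernel in self.kernels:
                    for model in self.models:
                        yield idx, group, scenario, kernel, model
                        idx += 1


def _cell_report(X, y, kernel_name: str, model: str, folds, grid: ExperimentGrid,
                 cell_seed: int):
    kernel = KernelSpec(kind=kernel_name)
    if model == "svm":
        result = tune_svm(X, y, kernel, folds, optimizer="none")
    elif model == "svm-ga":
        result = tune_svm(X, y, kernel, folds, optimizer="ga",
                          config=replace(grid.ga, seed=cell_seed))
    elif model == "svm-pso":
        result = tune_svm(X, y, kernel, folds, optimizer="pso",
                          config=replace(grid.pso, seed=cell_seed))
    else:
        raise ConfigurationError(f"unknown model {model!r}; choose from {MODELS}")
    return result


def run_grid(table: FeatureTable, grid: ExperimentGrid | None = None,
             existing: pd.DataFrame | None = None) -> pd.DataFrame:
    """Score every grid cell; one row per cell with pooled CV MSE and R^2.

    Deterministic under ``grid.seed``; cells present in ``existing``
    (matched on group/scenario/kernel/model) are carried over unchanged,
    and a failing cell is recorded with status 'error' while the grid
    continues.
    """
    grid = grid or ExperimentGrid()
    done = {}
    if existing is not None and len(existing):
        for _, row in existing.iterrows():
            done[(row["group"], row["scenario"], row["kernel"], row["model"])] = dict(row)

    # scenario views and folds are shared by all cells of a scenario
    views = {}
    for scenario in grid.scenarios:
        Xs, ys = scenario_target(table, scenario)
        folds = make_folds(len(Xs), k=grid.k_folds, seed=grid.seed)
        views[scenario] = (Xs, ys, folds)

    rows = []
    for idx, group, scenario, kernel, model in grid.cells():
        key = (group, scenario, kernel, model)
        if key in done:
            rows.append(done[key])
            continue
        Xs, ys, folds = views[scenario]
        Xg = Xs.loc[:, list(FEATURE_GROUPS[group])]
        cell_seed = grid.seed * 100_000 + idx
        row = {"group": group, "scenario": scenario, "kernel": kernel,
               "model": model, "seed": grid.seed}
        try:
            result = _cell_report(Xg, ys, kernel, model, folds, grid, cell_seed)
            row.update({"mse": result.report.mse, "r2": result.report.r2,
                        "n": result.report.n,
                        "best_param": float(result.report.metadata.get("best_param", np.nan)),
                        "tuned_parameter": result.tuned_parameter, "status": "ok"})
        except Exception as exc:
            logger.error("grid cell %s failed: %s", key, exc)
            row.update({"mse": np.nan, "r2": np.nan, "n": np.nan,
                        "best_param": np.nan, "tuned_parameter": "",
                        "status": f"error: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def run_importance(table: FeatureTable, group: str = "mirna",
                   scenario: str = "combined", kernel: KernelSpec | None = None,
                   estimator: str = "exact", n_samples: int = 1000,
                   seed: int = 0, k_folds: int = 5) -> BanzhafResult:
    """Banzhaf importance of one feature group under one scenario."""
    if group not in FEATURE_GROUPS:
        raise ConfigurationError(f"unknown group {group!r}; choose from {list(FEATURE_GROUPS)}")
    features = FEATURE_GROUPS[group]
    Xs, ys = scenario_target(table, scenario)
    folds = make_folds(len(Xs), k=k_folds, seed=seed)
    game = performance_characteristic(Xs.loc[:, list(features)], ys,
                                      kernel=kernel, folds=folds)
    meta = {"group": group, "scenario": scenario, "seed": seed}
    if estimator == "exact":
        return banzhaf_exact(features, game, metadata=meta)
    if estimator == "monte_carlo":
        return banzhaf_monte_carlo(features, game, n_samples=n_samples,
                                   seed=seed, metadata=meta)
    raise ConfigurationError(f"unknown estimator {estimator!r}")


def run_ablation(table: FeatureTable, drop_features: list[str] | tuple[str, ...],
                 base_features: tuple[str, ...] | None = None,
                 scenario: str = "combined", kernel: KernelSpec | None = None,
                 optimizer: str = "none", seed: int = 0, k_folds: int = 5,
                 optimizer_config=None) -> dict[str, CVReport]:
    """Re-score the model with ``drop_features`` removed.

    Returns {'full': CVReport, 'ablated': CVReport} on the same folds.
    """
    base = tuple(base_features) if base_features else table.features
    unknown = [f for f in drop_features if f not in base]
    if unknown:
        raise ConfigurationError(f"cannot drop unknown feature(s) {unknown}")
    reduced = tuple(f for f in base if f not in set(drop_features))
    if not reduced:
        raise ConfigurationError("ablation would drop every feature")

    Xs, ys = scenario_target(table, scenario)
    folds = make_folds(len(Xs), k=k_folds, seed=seed)
    kernel = kernel or KernelSpec()

    reports = {}
    for label, feats in (("full", base), ("ablated", reduced)):
        result = tune_svm(Xs.loc[:, list(feats)], ys, kernel, folds,
                          optimizer=optimizer, config=optimizer_config,
                          metadata={"ablation": label, "features": list(feats),
                                    "scenario": scenario})
        reports[label] = result.report
    return reports
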