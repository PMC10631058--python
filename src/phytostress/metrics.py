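"""Regression metrics and the k-fold cross-validation protocol.

MSE and R^2 are written out explicitly (they are the scoring contract
everything else is judged by) rather than pulled from a library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import ContractError, InvalidFoldsError, UndefinedMetricError

__all__ = ["mse", "r_squared", "make_folds", "cross_validate", "FoldAssignment", "CVReport"]


def _check_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    x_o = np.asarray(observed, dtype=float).ravel()
    x_p = np.asarray(predicted, dtype=float).ravel()
    if x_o.shape != x_p.shape:
        raise ContractError(f"length mismatch: {x_o.shape} vs {x_p.shape}")
    if x_o.size == 0:
        raise ContractError("empty prediction set")
    return x_o, x_p


def mse(observed, predicted) -> float:
    """Mean squared prediction error (1/n) * sum (x_p - x_o)^2."""
    x_o, x_p = _check_pair(observed, predicted)
    return float(np.mean((x_p - x_o) ** 2))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSres/SStot. Can be negative."""
    x_o, x_p = _check_pair(observed, predicted)
    if x_o.size < 2:
        raise UndefinedMetricError("R^2 requires at least two observations")
    ss_tot = float(np.sum((x_o - x_o.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined for constant observed values")
    ss_res = float(np.sum((x_p - x_o) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class FoldAssignment:
    """Per-record fold indices for k-fold cross-validation."""

    k: int
    indices: np.ndarray  # fold index in 0..k-1 per record
    seed: int | None = None
    grouped: bool = False

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices)
        if idx.min() < 0 or idx.max() >= self.k:
            raise InvalidFoldsError("fold indices out of range")

    @property
    def n(self) -> int:
        return len(self.indices)

    def split(self):
        """Yield (train_positions, test_positions) per fold."""
        pos = np.arange(self.n)
        for f in range(self.k):
            test = self.indices == f
            yield pos[~test], pos[test]


def make_folds(n: int, k: int = 5, seed: int = 0, groups=None) -> FoldAssignment:
    """Deterministic shuffled fold assignment; balanced sizes (within 1).

    With ``groups`` (e.g. pot ids), whole groups are kept in a single fold
    by greedily assigning shuffled groups to the currently smallest fold.
    """
    if k < 2:
        raise InvalidFoldsError("need at least 2 folds")
    if n < k:
        raise InvalidFoldsError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    if groups is None:
        order = rng.permutation(n)
        indices = np.empty(n, dtype=int)
        # contiguous chunks of the shuffled order, sizes differing by <= 1
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        start = 0
        for f, size in enumerate(sizes):
            indices[order[start:start + size]] = f
            start += size
        return FoldAssignment(k, indices, seed, grouped=False)

    groups = np.asarray(groups)
    if len(groups) != n:
        raise InvalidFoldsError("groups must have one entry per record")
    uniq = np.unique(groups)
    if len(uniq) < k:
        raise InvalidFoldsError(f"only {len(uniq)} groups for {k} folds")
    shuffled = rng.permutation(uniq)
    fold_sizes = np.zeros(k, dtype=int)
    indices = np.empty(n, dtype=int)
    for g in shuffled:
        members = groups == g
        f = int(np.argmin(fold_sizes))
        indices[members] = f
        fold_sizes[f] += int(members.sum())
    return FoldAssignment(k, indices, seed, grouped=True)


@dataclass
class CVReport:
    """Per-fold and pooled-out-of-fold MSE / R^2 for one model evaluation.

    The aggregate metrics are one pass over the pooled out-of-fold
    predictions of all records (all outputs concatenated for multi-output
    targets), not the mean of per-fold values.
    """

    fold_mse: list[float]
    fold_r2: list[float]
    mse: float
    r2: float
    n: int
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {"fold_mse": self.fold_mse, "fold_r2": self.fold_r2,
                   "mse": self.mse, "r2": self.r2, "n": self.n,
                   "metadata": self.metadata}
        return json.dumps(payload, indent=2, default=str)

    def to_csv_row(self) -> dict:
        row = dict(self.metadata)
        row.update({"mse": self.mse, "r2": self.r2, "n": self.n})
        return row


def cross_validate(model_factory: Callable[[], object], features, targets,
                   folds: FoldAssignment, metadata: dict | None = None) -> CVReport:
    """Train on k-1 folds, predict the held-out fold, for every fold.

    ``model_factory`` returns a fresh estimator with ``fit(X, y)`` and
    ``predict(X)``; ``targets`` may be (n,) or (n, m) for jointly
    evaluated outputs, whose residuals are pooled before the metrics.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(X) != len(y):
        raise ContractError("features and targets must have equal length")
    if len(X) != folds.n:
        raise InvalidFoldsError("fold assignment does not cover the records")

    oof = np.full(y.shape, np.nan, dtype=float)
    fold_mse, fold_r2 = [], []
    for fold_idx, (train, test) in enumerate(folds.split()):
        model = model_factory()
        try:
            model.fit(X[train], y[train])
            pred = np.asarray(model.predict(X[test]), dtype=float).reshape(y[test].shape)
        except Exception as exc:  # surface with fold context
            raise RuntimeError(f"model failure in fold {fold_idx}: {exc}") from exc
        oof[test] = pred
        fold_mse.append(mse(y[test], pred))
        try:
            fold_r2.append(r_squared(y[test], pred))
        except UndefinedMetricError:
            fold_r2.append(float("nan"))
    return CVReport(fold_mse, fold_r2, mse(y, oof), r_squared(y, oof),
                    n=folds.n, metadata=metadata or {})
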