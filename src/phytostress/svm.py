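"""Severity-prediction SVM: kernel definitions, target encoding, training.

The quadratic-program core is delegated to scikit-learn's SVR; the kernel
parameterization (gamma contract), feature standardization and the
multi-output scenario handling live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .exceptions import ConfigurationError, ContractError
from .metrics import CVReport, FoldAssignment, cross_validate

__all__ = [
    "KernelSpec",
    "kernel_matrix",
    "encode_target",
    "scenario_target",
    "SVMSeverityRegressor",
    "train_svm",
    "evaluate",
    "SCENARIOS",
]

KERNEL_KINDS = ("linear", "polynomial", "gaussian", "sigmoid")
SCENARIOS = ("drought", "salinity", "combined")

DEFAULT_C = 1.0
DEFAULT_EPSILON = 0.1


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus its scale parameter gamma.

    linear:      K(x, x') = x . x'
    polynomial:  K(x, x') = (gamma x . x' + coef0)^degree
    gaussian:    K(x, x') = exp(-gamma ||x - x'||^2)
    sigmoid:     K(x, x') = tanh(gamma x . x' + coef0)
    """

    kind: str = "gaussian"
    gamma: float = 1.0
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ConfigurationError(f"unknown kernel {self.kind!r}; choose from {KERNEL_KINDS}")
        if self.kind != "linear" and self.gamma <= 0:
            raise ConfigurationError("gamma must be positive")
        if self.kind == "polynomial" and self.degree < 2:
            raise ConfigurationError("polynomial degree must be >= 2")

    def with_gamma(self, gamma: float) -> "KernelSpec":
        return KernelSpec(self.kind, gamma, self.degree, self.coef0)


def kernel_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Explicit Gram matrix K[i, j] = K(X[i], Y[j]) for the four kernels."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    dot = X @ Y.T
    if spec.kind == "linear":
        return dot
    if spec.kind == "polynomial":
        return (spec.gamma * dot + spec.coef0) ** spec.degree
    if spec.kind == "sigmoid":
        return np.tanh(spec.gamma * dot + spec.coef0)
    sq = (X ** 2).sum(axis=1)[:, None] + (Y ** 2).sum(axis=1)[None, :] - 2.0 * dot
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


def encode_target(scenario: str, w, s) -> np.ndarray:
    """Numeric regression target(s) for a stress scenario.

    drought -> w; salinity -> s; combined -> the (w, s) pair as a
    two-column target evaluated jointly.
    """
    w = np.asarray(w, dtype=float)
    s = np.asarray(s, dtype=float)
    if scenario == "drought":
        return w
    if scenario == "salinity":
        return s
    if scenario == "combined":
        return np.column_stack([w, s])
    raise ConfigurationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def scenario_target(table, scenario: str, joint_code: bool = False):
    """Select the scenario's rows from a feature table and build targets.

    drought uses only salinity-control rows (s = 0), salinity only
    drought-control rows (w = 0), combined all rows. ``joint_code``
    switches the combined target to the single code 4*w + s for
    sensitivity analysis.
    """
    if scenario == "drought":
        sub = table.frame["s"] == 0
    elif scenario == "salinity":
        sub = table.frame["w"] == 0
    elif scenario == "combined":
        sub = pd.Series(True, index=table.frame.index)
    else:
        raise ConfigurationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    frame = table.frame.loc[sub]
    X = frame.loc[:, list(table.features)]
    w = frame["w"].to_numpy(dtype=float)
    s = frame["s"].to_numpy(dtype=float)
    if scenario == "combined" and joint_code:
        return X, 4.0 * w + s
    return X, encode_target(scenario, w, s)


class SVMSeverityRegressor:
    """Epsilon-SVR per output with train-time z-standardization.

    Standardization constants come from the training folds only, so
    cross-validation never leaks held-out statistics.
    """

    def __init__(self, kernel: KernelSpec | None = None, C: float = DEFAULT_C,
                 epsilon: float = DEFAULT_EPSILON):
        self.kernel = kernel or KernelSpec()
        self.C = C
        self.epsilon = epsilon
        self._models: list[SVR] = []
        self._mean: np.ndarray | None = None
        self._scale: np.ndarray | None = None
        self._n_outputs = 1

    _SKLEARN_KERNELS = {"linear": "linear", "polynomial": "poly",
                        "gaussian": "rbf", "sigmoid": "sigmoid"}

    # cap solver iterations: pathological gamma candidates proposed during
    # tuning can otherwise stall libsvm; well-posed fits stay far below this
    MAX_ITER = 100_000

    def _make_svr(self) -> SVR:
        return SVR(kernel=self._SKLEARN_KERNELS[self.kernel.kind],
                   gamma=self.kernel.gamma if self.kernel.kind != "linear" else "scale",
                   degree=self.kernel.degree, coef0=self.kernel.coef0,
                   C=self.C, epsilon=self.epsilon, max_iter=self.MAX_ITER)

    def fit(self, X, y) -> "SVMSeverityRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.unique(y).size < 2:
            raise ContractError("targets are degenerate (fewer than 2 distinct values)")
        self._mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        self._scale = scale
        Z = (X - self._mean) / self._scale
        ys = y[:, None] if y.ndim == 1 else y
        self._n_outputs = ys.shape[1]
        self._models = []
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # hitting MAX_ITER is expected for pathological tuning candidates
            warnings.simplefilter("ignore", ConvergenceWarning)
            for j in range(self._n_outputs):
                svr = self._make_svr()
                svr.fit(Z, ys[:, j])
                self._models.append(svr)
        return self

    def predict(self, X) -> np.ndarray:
        if not self._models:
            raise ContractError("model is not fitted")
        Z = (np.asarray(X, dtype=float) - self._mean) / self._scale
        preds = np.column_stack([m.predict(Z) for m in self._models])
        return preds[:, 0] if self._n_outputs == 1 else preds


def train_svm(features, targets, kernel: KernelSpec | None = None,
              C: float = DEFAULT_C, epsilon: float = DEFAULT_EPSILON) -> SVMSeverityRegressor:
    """Fit an :class:`SVMSeverityRegressor` on the full data."""
    return SVMSeverityRegressor(kernel, C, epsilon).fit(features, targets)


def evaluate(features, targets, kernel: KernelSpec | None = None,
             folds: FoldAssignment | None = None, C: float = DEFAULT_C,
             epsilon: float = DEFAULT_EPSILON, metadata: dict | None = None,
             seed: int = 0, k: int = 5) -> CVReport:
    """k-fold CV of the severity SVM; multi-output residuals are pooled."""
    X = np.asarray(features, dtype=float)
    if len(X) == 0:
        raise ContractError("scenario data is empty")
    if folds is None:
        from .metrics import make_folds
        folds = make_folds(len(X), k=k, seed=seed)
    kernel = kernel or KernelSpec()
    meta = {"kernel": kernel.kind, "gamma": kernel.gamma, "C": C, "epsilon": epsilon}
    meta.update(metadata or {})
    return cross_validate(lambda: SVMSeverityRegressor(kernel, C, epsilon),
                          X, targets, folds, metadata=meta)
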