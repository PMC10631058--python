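"""Banzhaf power-index feature importance.

A feature's raw index is its average marginal contribution to a
characteristic function v over all coalitions of the other features;
here v is the cross-validated R^2 of the severity SVM restricted to the
coalition. Exact enumeration for small groups, Monte-Carlo for larger.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .exceptions import ConfigurationError, UndefinedSharesError
from .metrics import FoldAssignment
from .svm import DEFAULT_C, DEFAULT_EPSILON, KernelSpec, evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "BanzhafResult",
    "CachedGame",
    "banzhaf_exact",
    "banzhaf_monte_carlo",
    "performance_characteristic",
    "normalize_shares",
]

EXACT_LIMIT = 15


def _shares_or_nan(raw: np.ndarray) -> np.ndarray:
    """Shares for an estimator result; NaN when all raw indices floor to 0."""
    try:
        return normalize_shares(raw)
    except UndefinedSharesError:
        logger.warning("all raw indices non-positive; percentage shares undefined")
        return np.full(len(raw), np.nan)


def normalize_shares(raw: Sequence[float]) -> np.ndarray:
    """Percentage shares: negative raw indices floored at 0, then
    normalized to sum to 100."""
    floored = np.maximum(np.asarray(raw, dtype=float), 0.0)
    total = floored.sum()
    if total <= 0.0:
        raise UndefinedSharesError("all raw indices are zero after flooring")
    return 100.0 * floored / total


@dataclass
class BanzhafResult:
    features: tuple[str, ...]
    raw: np.ndarray
    shares: np.ndarray  # percentages summing to 100
    standard_errors: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def ranking(self) -> list[str]:
        """Features ordered by decreasing share."""
        return [self.features[i] for i in np.argsort(-self.shares, kind="stable")]

    def to_json(self) -> str:
        payload = {
            "features": list(self.features),
            "raw": self.raw.tolist(),
            "share_percent": self.shares.tolist(),
            "standard_errors": None if self.standard_errors is None
            else self.standard_errors.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, default=str)

    def to_rows(self) -> list[dict]:
        rows = []
        for i, name in enumerate(self.features):
            rows.append({
                "feature": name,
                "raw_index": float(self.raw[i]),
                "share_percent": float(self.shares[i]),
                "standard_error": None if self.standard_errors is None
                else float(self.standard_errors[i]),
            })
        return rows


class CachedGame:
    """Wrap a coalition -> value callable with a per-run cache."""

    def __init__(self, fn: Callable[[frozenset], float], empty_value: float = 0.0):
        self._fn = fn
        self.empty_value = empty_value
        self.cache: dict[frozenset, float] = {}

    def __call__(self, coalition) -> float:
        key = frozenset(coalition)
        if not key:
            return self.empty_value
        if key not in self.cache:
            self.cache[key] = float(self._fn(key))
        return self.cache[key]


def banzhaf_exact(features: Sequence[str], v: Callable[[frozenset], float],
                  metadata: dict | None = None) -> BanzhafResult:
    """Exact Banzhaf indices by full coalition enumeration.

    beta_i = 2^-(n-1) * sum over C subset of N\\{i} of [v(C u {i}) - v(C)].
    """
    features = tuple(features)
    n = len(features)
    if n == 0:
        raise ConfigurationError("empty feature group")
    if n > EXACT_LIMIT:
        raise ConfigurationError(
            f"{n} features need 2^{n} coalition evaluations; "
            "use banzhaf_monte_carlo instead")
    game = v if isinstance(v, CachedGame) else CachedGame(v)

    raw = np.zeros(n)
    others = [tuple(f for f in features if f != feat) for feat in features]
    for i, feat in enumerate(features):
        total = 0.0
        for size in range(n):
            for combo in combinations(others[i], size):
                c = frozenset(combo)
                total += game(c | {feat}) - game(c)
        raw[i] = total / 2.0 ** (n - 1)

    return BanzhafResult(features, raw, _shares_or_nan(raw),
                         metadata={"estimator": "exact",
                                   "n_coalitions": 2 ** n, **(metadata or {})})


def banzhaf_monte_carlo(features: Sequence[str], v: Callable[[frozenset], float],
                        n_samples: int = 1000, seed: int = 0,
                        metadata: dict | None = None) -> BanzhafResult:
    """Unbiased Monte-Carlo Banzhaf estimate.

    For each feature, ``n_samples`` coalitions of the remaining features
    are drawn uniformly (each feature in/out with probability 1/2) and
    the marginal contributions averaged; standard errors are reported.
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    features = tuple(features)
    n = len(features)
    if n == 0:
        raise ConfigurationError("empty feature group")
    game = v if isinstance(v, CachedGame) else CachedGame(v)
    rng = np.random.default_rng(seed)

    raw = np.zeros(n)
    ses = np.zeros(n)
    for i, feat in enumerate(features):
        rest = [f for f in features if f != feat]
        marginals = np.empty(n_samples)
        for m in range(n_samples):
            include = rng.random(len(rest)) < 0.5
            c = frozenset(f for f, inc in zip(rest, include) if inc)
            marginals[m] = game(c | {feat}) - game(c)
        raw[i] = marginals.mean()
        ses[i] = marginals.std(ddof=1) / np.sqrt(n_samples) if n_samples > 1 else np.nan

    return BanzhafResult(features, raw, _shares_or_nan(raw), ses,
                         metadata={"estimator": "monte_carlo",
                                   "n_samples": n_samples, "seed": seed,
                                   **(metadata or {})})


def performance_characteristic(X, targets, kernel: KernelSpec | None = None,
                               folds: FoldAssignment | None = None,
                               C: float = DEFAULT_C, epsilon: float = DEFAULT_EPSILON,
                               seed: int = 0, k: int = 5) -> CachedGame:
    """Characteristic function v(coalition) = pooled CV R^2 of the SVM
    restricted to the coalition's feature columns.

    Folds are fixed once and shared across every coalition so that value
    differences reflect features, not resampling noise. v(empty) = 0; a
    coalition whose model fails to train also scores the empty value.
    """
    import pandas as pd

    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if folds is None:
        from .metrics import make_folds
        folds = make_folds(len(X), k=k, seed=seed)
    kernel = kernel or KernelSpec()

    def v(coalition: frozenset) -> float:
        cols = [c for c in X.columns if c in coalition]
        try:
            return evaluate(X.loc[:, cols], targets, kernel, folds,
                            C=C, epsilon=epsilon).r2
        except Exception as exc:
            logger.warning("coalition %s failed to train (%s); scoring empty value",
                           sorted(coalition), exc)
            return 0.0

    return CachedGame(v, empty_value=0.0)
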