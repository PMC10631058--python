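"""Synthetic stand-ins for the greenhouse experiment.

Generates (a) feature tables from a full-factorial drought x salinity
design with monotone per-feature stress responses plus Gaussian noise,
and (b) grayscale leaf-like images whose texture statistics trend with a
continuous stress severity. Everything is deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .data import FEATURES, ID_COLUMNS, FeatureTable
from .exceptions import ConfigurationError, InvalidDesignError

__all__ = [
    "StressDesign",
    "FeatureResponse",
    "FeatureResponseModel",
    "SyntheticDataset",
    "SyntheticLeafImageSpec",
    "generate_design",
    "generate_feature_table",
    "generate_leaf_image",
    "write_dataset",
    "default_response_model",
]


@dataclass(frozen=True)
class StressDesign:
    """Full-factorial layout: drought levels x salinity levels x replicates,
    each pot measured at ``time_points`` successive time points."""

    drought_levels: tuple[str, ...] = ("W0", "W1", "W2", "W3")
    salinity_levels: tuple[str, ...] = ("S0", "S1", "S2", "S3")
    replicates: int = 3
    time_points: int = 5
    sampling_interval_days: float = 3.0

    def __post_init__(self) -> None:
        if not self.drought_levels or not self.salinity_levels:
            raise InvalidDesignError("level lists must be non-empty")
        if self.replicates < 1 or self.time_points < 1:
            raise InvalidDesignError("replicates and time_points must be >= 1")
        if self.sampling_interval_days <= 0:
            raise InvalidDesignError("sampling_interval_days must be positive")

    @property
    def n_pots(self) -> int:
        return len(self.drought_levels) * len(self.salinity_levels) * self.replicates

    @property
    def n_records(self) -> int:
        return self.n_pots * self.time_points

    def iter_records(self) -> Iterable[dict]:
        """Enumerate pot x time-point records in deterministic order:
        drought level, then salinity level, then replicate, then time point."""
        for wi, wl in enumerate(self.drought_levels):
            for si, sl in enumerate(self.salinity_levels):
                for rep in range(1, self.replicates + 1):
                    pot = f"{wl}{sl}R{rep}"
                    for t in range(1, self.time_points + 1):
                        yield {
                            "pot_id": pot,
                            "replicate": rep,
                            "time_point": t,
                            "drought_level": wl,
                            "salinity_level": sl,
                            "w": wi,
                            "s": si,
                        }


def generate_design(
    drought_levels: int | Iterable[str] = 4,
    salinity_levels: int | Iterable[str] = 4,
    replicates: int = 3,
    time_points: int = 5,
    sampling_interval_days: float = 3.0,
) -> StressDesign:
    """Build a :class:`StressDesign`; level arguments may be counts or label lists."""
    if isinstance(drought_levels, int):
        if drought_levels < 1:
            raise InvalidDesignError("drought_levels must be >= 1")
        drought_levels = tuple(f"W{i}" for i in range(drought_levels))
    if isinstance(salinity_levels, int):
        if salinity_levels < 1:
            raise InvalidDesignError("salinity_levels must be >= 1")
        salinity_levels = tuple(f"S{i}" for i in range(salinity_levels))
    return StressDesign(
        tuple(drought_levels), tuple(salinity_levels), replicates, time_points,
        sampling_interval_days,
    )


@dataclass(frozen=True)
class FeatureResponse:
    """Linear response of one feature to the stress factors.

    value = baseline + drought_slope*w + salinity_slope*s
            + interaction*w*s + time_slope*(t-1) + N(0, noise_sd)
    """

    baseline: float
    drought_slope: float = 0.0
    salinity_slope: float = 0.0
    interaction: float = 0.0
    time_slope: float = 0.0
    noise_sd: float = 1.0
    direction: str = "mixed"  # up | down | mixed under increasing stress

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.direction not in {"up", "down", "mixed"}:
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.direction == "up" and (self.drought_slope < 0 or self.salinity_slope < 0):
            raise ConfigurationError("direction 'up' requires non-negative stress slopes")
        if self.direction == "down" and (self.drought_slope > 0 or self.salinity_slope > 0):
            raise ConfigurationError("direction 'down' requires non-positive stress slopes")

    def predict(self, w, s, t):
        """Noise-free linear predictor (time measured from the first sampling)."""
        return (
            self.baseline
            + self.drought_slope * np.asarray(w)
            + self.salinity_slope * np.asarray(s)
            + self.interaction * np.asarray(w) * np.asarray(s)
            + self.time_slope * (np.asarray(t) - 1)
        )


@dataclass(frozen=True)
class FeatureResponseModel:
    """Per-feature response parameters for every canonical feature."""

    responses: dict[str, FeatureResponse]

    def __post_init__(self) -> None:
        missing = [f for f in FEATURES if f not in self.responses]
        if missing:
            raise ConfigurationError(f"response model missing feature(s): {missing}")

    def __getitem__(self, name: str) -> FeatureResponse:
        return self.responses[name]

    def with_noise_sd(self, noise_sd: float) -> "FeatureResponseModel":
        return FeatureResponseModel(
            {k: replace(v, noise_sd=noise_sd) for k, v in self.responses.items()}
        )

    def scaled_noise(self, factor: float) -> "FeatureResponseModel":
        return FeatureResponseModel(
            {k: replace(v, noise_sd=v.noise_sd * factor) for k, v in self.responses.items()}
        )

    def to_dict(self) -> dict:
        return {
            "features": {
                name: {
                    "baseline": r.baseline,
                    "drought_slope": r.drought_slope,
                    "salinity_slope": r.salinity_slope,
                    "interaction": r.interaction,
                    "time_slope": r.time_slope,
                    "noise_sd": r.noise_sd,
                    "direction": r.direction,
                }
                for name, r in self.responses.items()
            }
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureResponseModel":
        if "features" not in payload:
            raise ConfigurationError("response model config must have a 'features' mapping")
        return cls({name: FeatureResponse(**params) for name, params in payload["features"].items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureResponseModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_response_model() -> FeatureResponseModel:
    """Default response parameters encoding the qualitative trends the
    analysis expects.

    Morphological texture statistics respond to total stress only and are
    noisy; physiological assays are moderately informative with partially
    differentiated drought/salinity slopes; miRNA concentrations are the
    most informative group, with miR-477b carrying the strongest (and most
    stress-type-specific) response and miR-399g a negligible one.
    Magnitudes are plausible placeholders, not calibrated to real assays.
    """
    r = FeatureResponse
    return FeatureResponseModel({
        # morphological: entropy falls, energy and homogeneity rise under stress
        "entropy":     r(4.00, -0.30, -0.20, 0.0, -0.020, 0.40, "down"),
        "energy":      r(0.18, 0.018, 0.026, 0.0, 0.0020, 0.035, "up"),
        "homogeneity": r(0.55, 0.015, 0.023, 0.0, 0.0010, 0.032, "up"),
        # physiological / biochemical
        "RWC": r(85.0, -5.0, -2.0, 0.0, -0.20, 3.2, "down"),
        "CI":  r(40.0, -2.5, -2.0, 0.0, 0.30, 2.4, "down"),
        "CA":  r(12.0, 2.2, 3.2, 0.2, 0.10, 1.7, "up"),
        "AC":  r(5.0, 0.8, 1.3, 0.0, 0.05, 0.8, "up"),
        "PhC": r(9.0, 1.6, 0.9, 0.0, 0.10, 1.1, "up"),
        "PC":  r(6.0, 1.2, 1.8, 0.0, 0.10, 1.3, "up"),
        # miRNA concentrations (arbitrary units)
        "miR-156a": r(10.0, 1.60, 0.40, 0.0, 0.02, 0.48, "up"),
        "miR-166i": r(8.0, 0.40, 1.60, 0.0, 0.02, 0.48, "up"),
        "miR-399g": r(5.0, 0.06, -0.05, 0.0, 0.01, 0.50, "mixed"),
        "miR-477b": r(12.0, 3.00, -2.60, 0.0, 0.02, 0.18, "mixed"),
    })


@dataclass
class SyntheticDataset:
    """A generated feature table plus the design/model/seed that produced it."""

    design: StressDesign
    model: FeatureResponseModel
    seed: int
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    def to_feature_table(self) -> FeatureTable:
        return FeatureTable(self.frame.copy())


def generate_feature_table(
    design: StressDesign,
    model: FeatureResponseModel | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw one realization of the feature table for ``design`` under ``model``.

    Each feature value is the linear predictor of its :class:`FeatureResponse`
    plus independent Gaussian noise; identical seeds reproduce identical
    tables bit-for-bit.
    """
    if model is None:
        model = default_response_model()
    records = pd.DataFrame(list(design.iter_records()))
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(len(records), len(FEATURES)))
    w = records["w"].to_numpy()
    s = records["s"].to_numpy()
    t = records["time_point"].to_numpy()
    for j, name in enumerate(FEATURES):
        resp = model[name]
        records[name] = resp.predict(w, s, t) + resp.noise_sd * noise[:, j]
    return SyntheticDataset(design, model, seed, records)


def write_dataset(dataset: SyntheticDataset | FeatureTable, path: str | Path,
                  fmt: str | None = None) -> Path:
    """Write a dataset in the raw-sheet layout (ids + labels + 13 features).

    Round-trips losslessly (within float formatting) through
    :func:`phytostress.data.load_feature_table`.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    frame = dataset.frame if isinstance(dataset, (SyntheticDataset, FeatureTable)) else dataset
    out = frame.loc[:, list(ID_COLUMNS) + list(FEATURES)]
    if fmt == "csv":
        out.to_csv(path, index=False, float_format="%.10g")
    elif fmt == "xlsx":
        out.to_excel(path, index=False)
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
    return path


# --------------------------------------------------------------------------
# leaf-like image synthesis


@dataclass(frozen=True)
class SyntheticLeafImageSpec:
    """Parameters for a leaf-like grayscale texture.

    Higher ``stress_severity`` produces coarser patches, fewer distinct
    gray values and less pixel noise, so GLCM entropy falls while energy
    and local homogeneity rise (in expectation over seeds).
    """

    size: tuple[int, int] = (64, 64)
    stress_severity: float = 0.0
    patch_size: int = 3
    gray_levels: int = 8
    noise_amp: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 16 or w < 16:
            raise ConfigurationError("image size must be at least 16x16")
        if not 0.0 <= self.stress_severity <= 3.0:
            raise ConfigurationError("stress_severity must lie in [0, 3]")
        if self.patch_size < 1 or self.gray_levels < 1:
            raise ConfigurationError("patch_size and gray_levels must be >= 1")
        if self.noise_amp < 0:
            raise ConfigurationError("noise_amp must be >= 0")


def generate_leaf_image(spec: SyntheticLeafImageSpec) -> np.ndarray:
    """Render the texture described by ``spec`` as a float image in [0, 1]."""
    h, w = spec.size
    sev = spec.stress_severity
    rng = np.random.default_rng(spec.seed)

    patch = max(1, round(spec.patch_size * (1.0 + sev)))
    n_levels = max(1, round(spec.gray_levels - 2.0 * sev))
    noise_sd = spec.noise_amp * (1.0 - sev / 4.0)

    gh = -(-h // patch)
    gw = -(-w // patch)
    if n_levels == 1:
        grid = np.full((gh, gw), 0.5)
    else:
        levels = 0.15 + 0.70 * np.arange(n_levels) / (n_levels - 1)
        grid = levels[rng.integers(0, n_levels, size=(gh, gw))]
    img = np.kron(grid, np.ones((patch, patch)))[:h, :w]
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(h, w))
    return np.clip(img, 0.0, 1.0)
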