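"""Leaf masking, gray-level co-occurrence matrices and texture statistics.

The GLCM is built here directly (it is the quantity the three statistics
are defined on); segmentation leans on scikit-image primitives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as sk_feature
from skimage import morphology as sk_morphology

from .exceptions import ConfigurationError, ContractError, DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "GLCM",
    "TextureFeatureVector",
    "to_grayscale",
    "segment_leaf",
    "quantize",
    "compute_glcm",
    "entropy",
    "energy",
    "local_homogeneity",
    "extract_features",
]

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

STANDARD_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 image to grayscale with BT.601 luma weights."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ConfigurationError(f"expected an HxWx3 image, got shape {rgb.shape}")
    return rgb @ np.asarray(LUMA_WEIGHTS)


def segment_leaf(gray: np.ndarray, sigma: float = 2.0,
                 low_threshold: float | None = None,
                 high_threshold: float | None = None) -> np.ndarray:
    """Boolean foreground mask: Canny edges, morphological closing, hole
    fill, then the largest connected component.

    Returns an all-True mask (with a warning) when no foreground region
    is found, so downstream GLCM computation falls back to the full frame.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ConfigurationError("segment_leaf expects a 2-D grayscale image")
    if min(gray.shape) < 8:
        raise ConfigurationError("image smaller than the smoothing kernel")

    edges = sk_feature.canny(gray, sigma=sigma, low_threshold=low_threshold,
                             high_threshold=high_threshold)
    closed = sk_morphology.closing(edges, sk_morphology.disk(3))
    filled = ndimage.binary_fill_holes(closed)
    labels, n = ndimage.label(filled)
    if n == 0:
        logger.warning("segment_leaf: no foreground region found; using full frame")
        return np.ones_like(gray, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def quantize(image: np.ndarray, levels: int,
             value_range: tuple[float, float] | None = None) -> np.ndarray:
    """Equal-width quantization of gray values into ``levels`` bins.

    Bin edges span ``value_range`` (default: [0, 1] for float images,
    [0, 2^bitdepth - 1] for integer images), so the result is invariant
    to shifts of the image within the declared range boundaries.
    """
    image = np.asarray(image)
    if levels < 2:
        raise ConfigurationError("levels must be >= 2")
    if value_range is None:
        if np.issubdtype(image.dtype, np.integer):
            value_range = (0, np.iinfo(image.dtype).max)
        else:
            value_range = (0.0, 1.0)
    lo, hi = value_range
    if not hi > lo:
        raise ConfigurationError("value_range must satisfy hi > lo")
    scaled = (np.asarray(image, dtype=float) - lo) / (hi - lo)
    return np.clip((scaled * levels).astype(int), 0, levels - 1)


@dataclass(frozen=True)
class GLCM:
    """Normalized co-occurrence probabilities over quantized gray levels."""

    p: np.ndarray
    offset: tuple[int, int]
    symmetric: bool
    pair_count: int

    def __post_init__(self) -> None:
        p = self.p
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ContractError("GLCM must be a square matrix")
        if (p < 0).any():
            raise ContractError("GLCM probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ContractError("GLCM probabilities must sum to 1")
        if self.symmetric and not np.array_equal(p, p.T):
            raise ContractError("symmetric GLCM must equal its transpose")

    @property
    def levels(self) -> int:
        return self.p.shape[0]


def compute_glcm(image: np.ndarray, levels: int = 8,
                 offset: tuple[int, int] = (0, 1), symmetric: bool = True,
                 mask: np.ndarray | None = None,
                 value_range: tuple[float, float] | None = None) -> GLCM:
    """Count co-occurrences of quantized gray levels under ``offset``.

    A pixel pair contributes only when both endpoints lie inside ``mask``
    (pairs straddling the mask border are discarded). With ``symmetric``
    the transpose is added before normalization.
    """
    q = quantize(image, levels, value_range)
    if mask is None:
        mask = np.ones(q.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != q.shape:
        raise ConfigurationError("mask shape must equal image shape")

    dr, dc = offset
    h, w = q.shape
    r0 = max(0, -dr); r1 = min(h, h - dr)
    c0 = max(0, -dc); c1 = min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise DegenerateInputError(f"offset {offset} admits no pixel pairs")

    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise DegenerateInputError("no valid in-mask pixel pairs under the offset")

    counts = np.zeros((levels, levels))
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), (dr, dc), symmetric, n_pairs)


_LOG_DIVISORS = {"e": 1.0, "natural": 1.0, 2: math.log(2.0), 10: math.log(10.0),
                 "2": math.log(2.0), "10": math.log(10.0)}


def entropy(glcm: GLCM, log_base: str | int = "e") -> float:
    """-sum p log p over the GLCM, with 0 log 0 = 0. Natural log by default."""
    if log_base not in _LOG_DIVISORS:
        raise ConfigurationError(f"log_base must be one of 'e', 2, 10; got {log_base!r}")
    p = glcm.p[glcm.p > 0]
    return float(-(p * np.log(p)).sum() / _LOG_DIVISORS[log_base])


def energy(glcm: GLCM) -> float:
    """Sum of squared co-occurrence probabilities, in (0, 1]."""
    return float((glcm.p ** 2).sum())


def local_homogeneity(glcm: GLCM) -> float:
    """Sum of p(i,j) / (1 + (i-j)^2), in (0, 1]."""
    idx = np.arange(glcm.levels)
    weights = 1.0 / (1.0 + (idx[:, None] - idx[None, :]) ** 2)
    return float((glcm.p * weights).sum())


@dataclass(frozen=True)
class TextureFeatureVector:
    entropy: float
    energy: float
    homogeneity: float

    def __post_init__(self) -> None:
        if self.entropy < -1e-12:
            raise ContractError("entropy must be non-negative")
        if not 0.0 < self.energy <= 1.0 + 1e-12:
            raise ContractError("energy must lie in (0, 1]")
        if not 0.0 < self.homogeneity <= 1.0 + 1e-12:
            raise ContractError("local homogeneity must lie in (0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {"entropy": self.entropy, "energy": self.energy,
                "homogeneity": self.homogeneity}


def extract_features(image: np.ndarray, mask: np.ndarray | None = None,
                     levels: int = 8, offset: tuple[int, int] = (0, 1),
                     symmetric: bool = True, log_base: str | int = "e",
                     value_range: tuple[float, float] | None = None,
                     average_directions: bool = False) -> TextureFeatureVector:
    """Entropy, energy and local homogeneity from one GLCM (or, with
    ``average_directions``, the mean over the four standard offsets)."""
    offsets = STANDARD_OFFSETS if average_directions else (offset,)
    ent = ene = hom = 0.0
    for off in offsets:
        glcm = compute_glcm(image, levels=levels, offset=off, symmetric=symmetric,
                            mask=mask, value_range=value_range)
        ent += entropy(glcm, log_base)
        ene += energy(glcm)
        hom += local_homogeneity(glcm)
    k = len(offsets)
    return TextureFeatureVector(ent / k, ene / k, hom / k)
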