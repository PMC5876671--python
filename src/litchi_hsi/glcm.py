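"""Gray-level co-occurrence matrix and the 7-dimensional texture descriptor.

The GLCM is the normalized joint distribution of quantized intensity pairs at
a fixed pixel offset; counts are accumulated over four directions (0, 45, 90,
135 degrees), restricted to pixel pairs lying inside the analysis mask,
symmetrized by adding the transpose, and normalized to sum 1.  From it the
litchi workflow takes contrast, correlation, energy, homogeneity, variance
(of the GLCM marginal), the region mean gray level (normalized to [0, 1]) and
entropy (natural log).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

FEATURE_NAMES = ("contrast", "correlation", "energy", "homogeneity",
                 "variance", "mean", "entropy")

# row/col steps per angle (degrees), following the usual image convention
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCM:
    matrix: np.ndarray             # levels x levels, sums to 1
    levels: int
    distance: int
    angles: tuple[int, ...]
    symmetric: bool
    n_pairs: int

    def __post_init__(self) -> None:
        if abs(self.matrix.sum() - 1.0) > 1e-9:
            raise ValueError("GLCM must be normalized to sum 1")


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    variance: float
    mean: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def quantize(image: np.ndarray, mask: np.ndarray | None = None, levels: int = 64) -> np.ndarray:
    """Linear binning of [0, 255] into ``levels`` bins; -1 marks out-of-mask."""
    if not 2 <= levels <= 256:
        raise ValueError("levels must be in [2, 256]")
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty mask")
    q = np.minimum((img.astype(np.int64) * levels) // 256, levels - 1)
    q[~mask] = -1
    return q


def compute_glcm(
    qimage: np.ndarray,
    distance: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence counts over the given offsets, masked, normalized.

    ``qimage`` is a quantized image with -1 at excluded pixels.  A pair is
    counted only when both ends are inside the mask.
    """
    q = np.asarray(qimage, dtype=np.int64)
    levels = int(q.max()) + 1
    if levels < 1:
        raise ValueError("quantized image has no in-mask pixels")
    counts = np.zeros((levels, levels), dtype=np.float64)
    rows, cols = q.shape
    for angle in angles:
        if angle not in _ANGLE_OFFSETS:
            raise ValueError(f"unsupported angle {angle}; use 0/45/90/135")
        dr, dc = _ANGLE_OFFSETS[angle]
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = (a >= 0) & (b >= 0)
        if valid.any():
            np.add.at(counts, (a[valid], b[valid]), 1.0)
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise ValueError("no valid pixel pairs for the requested offsets")
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), levels, distance, tuple(angles), symmetric, n_pairs)


def texture_features(glcm: GLCM, qimage: np.ndarray) -> TextureFeatures:
    """The 7 texture statistics of a GLCM plus its source region.

    With zero marginal variance (single occupied level) the correlation is
    defined as 1 — the degenerate perfectly-correlated case — and logged.
    """
    P = glcm.matrix
    levels = glcm.levels
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    contrast = float((((ii - jj) ** 2) * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float((i * p_i).sum())
    mu_j = float((i * p_j).sum())
    var_i = float((((i - mu_i) ** 2) * p_i).sum())
    var_j = float((((i - mu_j) ** 2) * p_j).sum())
    if var_i <= 1e-15 or var_j <= 1e-15:
        log.info("texture_features: zero marginal variance; correlation := 1")
        correlation = 1.0
    else:
        correlation = float((((ii - mu_i) * (jj - mu_j) * P).sum())
                            / np.sqrt(var_i * var_j))

    q = np.asarray(qimage, dtype=np.int64)
    in_mask = q[q >= 0]
    mean = float(in_mask.mean() / max(levels - 1, 1)) if in_mask.size else 0.0

    return TextureFeatures(contrast, correlation, energy, homogeneity, var_i, mean, entropy)


def region_features(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = 64,
    distance: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> TextureFeatures:
    """Quantize a masked gray region and compute its 7 texture features."""
    q = quantize(image, mask, levels)
    g = compute_glcm(q, distance=distance, angles=angles, symmetric=True)
    return texture_features(g, q)
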