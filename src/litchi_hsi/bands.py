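"""Image-level PCA across bands and characteristic-wavelength selection.

Fruit-masked pixels (pooled across one or more reflectance cubes) form a
pixels x bands matrix whose band covariance is eigen-decomposed.  Each
principal component contributes ``100 * eigenvalue / sum(eigenvalues)``
percent of the variance; its loading (weight-coefficient) vector assigns one
coefficient per band.  Characteristic wavelengths are read off the local
extrema of a chosen component's loading curve — the selection the litchi
workflow applies to PC3, where the damage-sensitive bands near 694, 725 and
798 nm appear as loading extrema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import peak_prominences, savgol_filter

from .hsi_io import ReflectanceCube, WavelengthAxis


@dataclass
class PixelMatrix:
    data: np.ndarray               # pixels x bands
    axis: WavelengthAxis
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.axis):
            raise ValueError("pixel matrix must be pixels x bands matching the axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("pixel matrix contains non-finite values")


@dataclass
class PCAResult:
    band_means: np.ndarray
    loadings: np.ndarray           # bands x n_pc, columns unit-norm
    eigenvalues: np.ndarray        # all bands, descending
    contribution: np.ndarray       # percent, for the stored PCs
    cumulative: np.ndarray         # percent, for the stored PCs
    axis: WavelengthAxis

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]

    def contribution_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pc": np.arange(1, self.n_pc + 1),
            "eigenvalue": self.eigenvalues[: self.n_pc],
            "contribution_%": self.contribution,
            "cumulative_%": self.cumulative,
        })

    def loading_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"wavelength_nm": self.axis.values})
        for k in range(self.n_pc):
            df[f"pc{k + 1}"] = self.loadings[:, k]
        return df


@dataclass
class CharacteristicBands:
    wavelengths: np.ndarray        # nm, ascending
    source_pc: int                 # 1-based
    extremum_types: list[str]      # 'max' / 'min', aligned with wavelengths
    prominences: np.ndarray

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({
            "wavelengths_nm": self.wavelengths.tolist(),
            "source_pc": self.source_pc,
            "extremum_types": self.extremum_types,
            "prominences": self.prominences.tolist(),
        }))
        return path


def assemble_pixels(
    cubes: list[ReflectanceCube],
    masks: list[np.ndarray],
    max_pixels: int = 50_000,
    seed: int = 0,
) -> PixelMatrix:
    """Pool masked pixels from several cubes, subsampled to ``max_pixels``."""
    if len(cubes) != len(masks) or not cubes:
        raise ValueError("need one mask per cube")
    blocks = []
    for cube, mask in zip(cubes, masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cube.shape[:2]:
            raise ValueError("mask shape does not match cube")
        blocks.append(cube.data[mask])
    pooled = np.concatenate(blocks, axis=0)
    if pooled.shape[0] == 0:
        raise ValueError("union of masks is empty")
    if pooled.shape[0] > max_pixels:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(pooled.shape[0], size=max_pixels, replace=False))
        pooled = pooled[idx]
    return PixelMatrix(pooled, cubes[0].axis,
                       provenance={"n_cubes": len(cubes), "seed": seed})


def image_pca(pixels: PixelMatrix, n_pc: int = 7) -> PCAResult:
    """Eigen-decomposition of the band covariance of centered pixels.

    Loading signs are fixed so each column's largest-magnitude entry is
    positive; contribution rates use the full eigenvalue spectrum in the
    denominator.
    """
    X = pixels.data
    n, p = X.shape
    if n < n_pc or p < n_pc:
        raise ValueError(f"need at least {n_pc} pixels and bands")
    means = X.mean(axis=0)
    Xc = X - means
    cov = (Xc.T @ Xc) / max(n - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("pixel matrix has zero variance")
    loadings = evecs[:, :n_pc].copy()
    for k in range(n_pc):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
    contribution = 100.0 * evals[:n_pc] / total
    return PCAResult(means, loadings, evals, contribution,
                     np.cumsum(contribution), pixels.axis)


def score_image(cube: ReflectanceCube, pca: PCAResult, pc_index: int) -> np.ndarray:
    """Per-pixel projection on one loading, min-max rescaled to 0..255.

    ``pc_index`` is 1-based.  A constant projection maps to all zeros.
    """
    if not 1 <= pc_index <= pca.n_pc:
        raise ValueError(f"pc_index must be in [1, {pca.n_pc}]")
    proj = (cube.data.astype(np.float64) - pca.band_means) @ pca.loadings[:, pc_index - 1]
    lo, hi = proj.min(), proj.max()
    if hi - lo < 1e-12:
        return np.zeros(proj.shape, dtype=np.uint8)
    return np.round(255.0 * (proj - lo) / (hi - lo)).astype(np.uint8)


def band_image(cube: ReflectanceCube, nm: float, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Single-band grayscale image on a fixed reflectance scale.

    Reflectance in ``[lo, hi]`` maps linearly to 0..255 (clipped), so gray
    levels stay comparable across samples — unlike the per-image min-max
    stretch used for score images.
    """
    band = cube.data[:, :, cube.axis.nearest_index(nm)].astype(np.float64)
    scaled = np.clip((band - lo) / (hi - lo), 0.0, 1.0)
    return np.round(255.0 * scaled).astype(np.uint8)


def pc_loading_extrema(
    pca: PCAResult,
    pc_index: int = 3,
    smooth_window: int = 7,
    min_prominence_frac: float = 0.05,
) -> CharacteristicBands:
    """Characteristic wavelengths from local extrema of one loading curve.

    The loading is SG-smoothed, interior sign changes of the first difference
    mark candidate extrema, and those whose prominence reaches
    ``min_prominence_frac`` of the smoothed curve's range are kept.
    """
    if not 1 <= pc_index <= pca.n_pc:
        raise ValueError(f"pc_index must be in [1, {pca.n_pc}]")
    curve = pca.loadings[:, pc_index - 1]
    if curve.size >= smooth_window > 2:
        curve = savgol_filter(curve, smooth_window, 2, mode="mirror")
    rng_ = curve.max() - curve.min()
    if rng_ < 1e-15:
        return CharacteristicBands(np.array([]), pc_index, [], np.array([]))
    threshold = min_prominence_frac * rng_

    d = np.diff(curve)
    sign = np.sign(d)
    # carry the previous sign across flat segments so plateaus count once
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    idx_max = [i for i in range(1, curve.size - 1) if sign[i - 1] > 0 and sign[i] < 0]
    idx_min = [i for i in range(1, curve.size - 1) if sign[i - 1] < 0 and sign[i] > 0]

    found: list[tuple[float, str, float]] = []
    if idx_max:
        prom = peak_prominences(curve, idx_max)[0]
        found += [(pca.axis.values[i], "max", p) for i, p in zip(idx_max, prom) if p >= threshold]
    if idx_min:
        prom = peak_prominences(-curve, idx_min)[0]
        found += [(pca.axis.values[i], "min", p) for i, p in zip(idx_min, prom) if p >= threshold]
    found.sort(key=lambda t: t[0])
    return CharacteristicBands(
        np.array([f[0] for f in found]), pc_index,
        [f[1] for f in found], np.array([f[2] for f in found]),
    )
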