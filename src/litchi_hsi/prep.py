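"""ROI spectrum extraction and chemometric preprocessing.

A sample spectrum is the per-band arithmetic mean over a 50 x 50 pixel region
of interest placed on the pericarp (over the damage site for bruised fruit).
Spectra are then conditioned for modeling with Savitzky-Golay smoothing,
minimum-subtraction baseline correction and least-squares detrending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .hsi_io import ReflectanceCube, WavelengthAxis


@dataclass(frozen=True)
class ROIWindow:
    """Square pixel window, default 50 x 50, addressed by its center."""

    center_row: int
    center_col: int
    size: int = 50

    def bounds(self) -> tuple[int, int, int, int]:
        half = self.size // 2
        r0 = self.center_row - half
        c0 = self.center_col - half
        return r0, r0 + self.size, c0, c0 + self.size


@dataclass
class MeanSpectrum:
    values: np.ndarray
    axis: WavelengthAxis
    sample_id: str = ""
    label: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size != len(self.axis):
            raise ValueError("spectrum length must match wavelength axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class SpectrumTable:
    """Stacked sample spectra: X (samples x bands), labels y, shared axis."""

    X: np.ndarray
    y: np.ndarray
    axis: WavelengthAxis
    sample_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match label vector length")
        if self.X.shape[1] != len(self.axis):
            raise ValueError("X columns must match wavelength axis")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def extract_roi_mean(cube: ReflectanceCube, roi: ROIWindow, sample_id: str = "",
                     label: int = -1) -> MeanSpectrum:
    """Per-band mean reflectance over the ROI window."""
    r0, r1, c0, c1 = roi.bounds()
    rows, cols, _ = cube.shape
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ValueError(
            f"ROI [{r0}:{r1}, {c0}:{c1}] falls outside the {rows}x{cols} image"
        )
    window = cube.data[r0:r1, c0:c1, :]
    mean = window.mean(axis=(0, 1), dtype=np.float64)
    return MeanSpectrum(mean, cube.axis, sample_id=sample_id, label=label)


def roi_for_sample(fruit_mask: np.ndarray, damage_mask: np.ndarray, size: int = 50) -> ROIWindow:
    """ROI centered on the damage centroid, or the fruit centroid when intact.

    The center is clamped so the window stays inside the image.
    """
    target = damage_mask if damage_mask.any() else fruit_mask
    if not target.any():
        raise ValueError("empty fruit mask")
    rr, cc = np.nonzero(target)
    r, c = int(round(rr.mean())), int(round(cc.mean()))
    half = size // 2
    r = min(max(r, half), fruit_mask.shape[0] - (size - half))
    c = min(max(c, half), fruit_mask.shape[1] - (size - half))
    return ROIWindow(r, c, size)


def sg_smooth(spectrum: MeanSpectrum, window: int = 11, polyorder: int = 2) -> MeanSpectrum:
    """Savitzky-Golay smoothing.

    Endpoints use the polynomial-interpolation extension so that any signal
    that is itself a polynomial of degree <= polyorder passes through
    unchanged — the defining exactness property of the filter.
    """
    n = spectrum.values.size
    if window % 2 == 0 or window <= polyorder or window > n:
        raise ValueError(f"invalid SG parameters window={window}, polyorder={polyorder} for {n} bands")
    smoothed = savgol_filter(spectrum.values, window, polyorder, mode="interp")
    return MeanSpectrum(smoothed, spectrum.axis, spectrum.sample_id, spectrum.label)


def detrend_baseline(spectrum: MeanSpectrum, mode: str = "both") -> MeanSpectrum:
    """Baseline correction and/or detrending.

    ``baseline`` subtracts the per-spectrum minimum; ``detrend`` subtracts the
    least-squares line over wavelength; ``both`` applies baseline then detrend.
    """
    if mode not in ("baseline", "detrend", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    v = spectrum.values.copy()
    if v.size < 3:
        raise ValueError("spectrum too short")
    if mode in ("baseline", "both"):
        v = v - v.min()
    if mode in ("detrend", "both"):
        lam = spectrum.axis.values
        coeffs = np.polynomial.polynomial.polyfit(lam, v, 1)
        v = v - np.polynomial.polynomial.polyval(lam, coeffs)
    return MeanSpectrum(v, spectrum.axis, spectrum.sample_id, spectrum.label)


def preprocess(spectrum: MeanSpectrum, sg_window: int = 11, sg_polyorder: int = 2,
               mode: str | None = "both") -> MeanSpectrum:
    """The full conditioning chain: SG smoothing, then baseline/detrend."""
    out = sg_smooth(spectrum, sg_window, sg_polyorder)
    if mode is not None:
        out = detrend_baseline(out, mode)
    return out


def build_table(samples: list[MeanSpectrum]) -> SpectrumTable:
    """Stack spectra sharing one wavelength axis into a SpectrumTable."""
    if not samples:
        raise ValueError("no spectra supplied")
    axis = samples[0].axis
    for s in samples[1:]:
        if len(s.axis) != len(axis) or not np.allclose(s.axis.values, axis.values):
            raise ValueError("spectra have mismatched wavelength axes")
    X = np.vstack([s.values for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    ids = [s.sample_id for s in samples]
    return SpectrumTable(X, y, axis, sample_ids=ids)


def table_to_csv(table: SpectrumTable, path: str | Path) -> Path:
    """CSV layout: sample id, label, then one column per wavelength (nm)."""
    path = Path(path)
    cols = {"sample_id": table.sample_ids or [f"s{i}" for i in range(table.n_samples)],
            "label": table.y}
    for j, nm in enumerate(table.axis.values):
        cols[f"{nm:.6g}"] = table.X[:, j]
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")
    return path


def table_from_csv(path: str | Path) -> SpectrumTable:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    axis = WavelengthAxis(np.array([float(c) for c in wl_cols]))
    return SpectrumTable(df[wl_cols].to_numpy(float), df["label"].to_numpy(int), axis,
                         sample_ids=[str(s) for s in df["sample_id"]])
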