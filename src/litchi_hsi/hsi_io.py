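"""Hyperspectral cube I/O and reflectance calibration.

Cubes are stored in a minimal ENVI dialect: a raw binary file plus a text
header declaring ``samples`` (columns), ``lines`` (rows), ``bands``, the data
type, the interleave and the wavelength list in nm.  Only the two layouts that
line-scan VNIR instruments actually emit are supported (BSQ and BIL), raw
counts as little-endian unsigned 16-bit and reflectance as 32-bit float.

Calibration converts raw sensor counts ``I0`` to relative reflectance using a
white-reference frame ``W`` (a ~99 % reflectance board) and a dark-current
frame ``D`` (lens capped)::

    I = (I0 - D) / (W - D)

applied per pixel and band.  Pixels where ``W - D`` is numerically zero are
set to reflectance 0 and counted; output is clipped to ``[0, clip_hi]`` so
specular highlights cannot poison downstream statistics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)

#: default spectral grid: 215 bands at 2.8 nm starting at 400 nm (ends 999.2)
DEFAULT_N_BANDS = 215
DEFAULT_START_NM = 400.0
DEFAULT_STEP_NM = 2.8

_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_ENVI_CODES = {np.dtype("<f4"): 4, np.dtype("<u2"): 12}


@dataclass(frozen=True)
class WavelengthAxis:
    """Ordered band-center wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength axis must be a 1-D array of >= 2 bands")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def nearest_index(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.values - nm)))

    def nearest(self, nm: float) -> float:
        return float(self.values[self.nearest_index(nm)])


def default_axis(
    n_bands: int = DEFAULT_N_BANDS,
    start_nm: float = DEFAULT_START_NM,
    step_nm: float = DEFAULT_STEP_NM,
) -> WavelengthAxis:
    """The instrument grid: 400–999.2 nm at 2.8 nm resolution (215 bands)."""
    return WavelengthAxis(start_nm + step_nm * np.arange(n_bands))


@dataclass
class RawCube:
    """Raw sensor counts, rows x cols x bands."""

    data: np.ndarray
    axis: WavelengthAxis
    interleave: str = "bsq"
    source: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"cube has {self.data.shape[2]} bands but axis lists {len(self.axis)}"
            )
        if np.any(self.data < 0):
            raise ValueError("raw counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReflectanceCube:
    """Relative reflectance, rows x cols x bands, clipped to [0, 1.5]."""

    data: np.ndarray
    axis: WavelengthAxis
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.data.shape[2] != len(self.axis):
            raise ValueError("band count does not match wavelength axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class ReferenceFrames:
    """White and dark reference frames, broadcastable to a cube.

    Accepted shapes: full image ``(rows, cols, bands)``, per-column line-scan
    references ``(cols, bands)``, per-pixel scalars ``(rows, cols, 1)``, or a
    single spectrum ``(bands,)``.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if not np.all(np.mean(self.white) > np.mean(self.dark)):
            raise ValueError("white frame must exceed dark frame on average")

    def broadcast_to(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        def up(a: np.ndarray) -> np.ndarray:
            if a.ndim == 1:  # spectrum
                a = a[None, None, :]
            elif a.ndim == 2:  # per-column (line-scan convention)
                a = a[None, :, :]
            return np.broadcast_to(a, shape)

        return up(self.white), up(self.dark)


# ---------------------------------------------------------------------------
# ENVI dialect
# ---------------------------------------------------------------------------

def _parse_header(text: str) -> dict:
    """Parse `key = value` pairs; `{...}` blocks may span lines."""
    text = re.sub(r"^ENVI\s*", "", text.strip())
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.M | re.S)
    # join multi-line {...} blocks first
    joined = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for m in pattern.finditer(joined):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_envi(cube_path: str | Path, header_path: str | Path | None = None) -> RawCube | ReflectanceCube:
    """Read a cube from a binary file + text header.

    Returns a :class:`RawCube` for integer data and a :class:`ReflectanceCube`
    for float data.  Row-major, origin top-left, 0-based indexing.
    """
    cube_path = Path(cube_path)
    if header_path is None:
        header_path = cube_path.with_suffix(".hdr")
    fields = _parse_header(Path(header_path).read_text())

    for key in ("samples", "lines", "bands", "data type", "interleave", "wavelength"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required field '{key}'")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    code = int(fields["data type"])
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unsupported interleave '{interleave}' (BSQ/BIL only)")
    if int(fields.get("byte order", "0")) != 0:
        raise ValueError("only little-endian (byte order = 0) is supported")
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = _ENVI_DTYPES[code]

    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()])
    if wavelengths.size != bands:
        raise ValueError(
            f"header lists {wavelengths.size} wavelengths for {bands} bands"
        )

    flat = np.fromfile(cube_path, dtype=dtype)
    if flat.size != rows * cols * bands:
        raise ValueError(
            f"file holds {flat.size} values, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":  # bands, rows, cols
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:  # bil: rows, bands, cols
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)

    axis = WavelengthAxis(wavelengths)
    if dtype == np.dtype("<f4"):
        return ReflectanceCube(data.astype(np.float32), axis)
    return RawCube(np.ascontiguousarray(data), axis, interleave=interleave, source=str(cube_path))


def write_envi(cube: RawCube | ReflectanceCube, out_prefix: str | Path, interleave: str = "bsq") -> tuple[Path, Path]:
    """Write ``<prefix>.img`` + ``<prefix>.hdr``.

    Raw counts are stored as unsigned 16-bit, reflectance as 32-bit float.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil"):
        raise ValueError("interleave must be 'bsq' or 'bil'")
    out_prefix = Path(out_prefix)
    img_path = out_prefix.with_suffix(".img")
    hdr_path = out_prefix.with_suffix(".hdr")

    if isinstance(cube, ReflectanceCube):
        arr = cube.data.astype("<f4")
    else:
        arr = np.round(cube.data).astype("<u2")
    rows, cols, bands = arr.shape
    if interleave == "bsq":
        flat = arr.transpose(2, 0, 1)
    else:
        flat = arr.transpose(0, 2, 1)

    img_path.parent.mkdir(parents=True, exist_ok=True)
    flat.tofile(img_path)
    wl = ", ".join(f"{w:.6g}" for w in cube.axis.values)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[arr.dtype.newbyteorder('<')]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return img_path, hdr_path


# ---------------------------------------------------------------------------
# Calibration and band trimming
# ---------------------------------------------------------------------------

def calibrate(
    raw: RawCube,
    refs: ReferenceFrames,
    clip_hi: float = 1.5,
) -> ReflectanceCube:
    """Reflectance calibration ``I = (I0 - D) / (W - D)``.

    Pixels whose white/dark difference falls below ``1e-6 * max(W)`` get
    reflectance 0; their count is logged and stored on the result as
    ``n_degenerate``.  Output is clipped to ``[0, clip_hi]``.
    """
    white, dark = refs.broadcast_to(raw.shape)
    w_max = float(np.max(white))
    if w_max <= 0:
        raise ValueError("white frame is all zeros")
    eps = 1e-6 * w_max
    denom = white - dark
    bad = denom <= eps
    n_bad = int(np.count_nonzero(bad))
    safe = np.where(bad, 1.0, denom)
    refl = (raw.data.astype(np.float64) - dark) / safe
    refl[bad] = 0.0
    n_clip = int(np.count_nonzero((refl < 0) | (refl > clip_hi)))
    refl = np.clip(refl, 0.0, clip_hi)
    if n_bad:
        log.warning("calibrate: %d degenerate pixels (W - D <= eps) set to 0", n_bad)
    if n_clip:
        log.info("calibrate: %d values clipped to [0, %.3g]", n_clip, clip_hi)
    return ReflectanceCube(refl.astype(np.float32), raw.axis, n_degenerate=n_bad)


def trim_bands(cube: ReflectanceCube, lo_nm: float, hi_nm: float) -> ReflectanceCube:
    """Keep bands with ``lo_nm <= wavelength <= hi_nm``."""
    if lo_nm >= hi_nm:
        raise ValueError("lo must be < hi")
    keep = (cube.axis.values >= lo_nm) & (cube.axis.values <= hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands within [{lo_nm}, {hi_nm}] nm")
    return ReflectanceCube(
        cube.data[:, :, keep], WavelengthAxis(cube.axis.values[keep]),
        n_degenerate=cube.n_degenerate,
    )
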