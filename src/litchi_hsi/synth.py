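"""Synthetic litchi hyperspectral scenes.

Generates labeled, litchi-like raw cubes with white/dark reference frames and
ground-truth masks.  The emulated statistical structure mirrors what the
analysis downstream assumes about 400–1000 nm pericarp reflectance:

* a smooth base curve with clear features only inside 450–850 nm — a green
  anthocyanin-region bump near 560 nm, a red-edge step near 685 nm and a
  browning trough near 746 nm;
* four quality classes (0 fresh, 1 newly damaged, 2 two hours after damage,
  3 four hours after damage) whose curves diverge monotonically with damage
  age across 694–798 nm;
* a spatially localized damage blob (rough boundary) carrying an additional
  reflectance depression centered near 746 nm and doubled spatial texture
  noise;
* per-pixel band noise whose standard deviation triples below 450 nm and
  above 850 nm, plus a smooth multiplicative illumination field;
* raw counts synthesized by inverting the reflectance calibration,
  ``I0 = D + (W - D) * R + noise``, so that calibrating a sample with its own
  reference frames recovers the reflectance field.

None of the numeric shape parameters are measured litchi values; they are
stand-ins chosen to reproduce the qualitative structure above and are exposed
here and in the pipeline configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .hsi_io import RawCube, ReferenceFrames, ReflectanceCube, WavelengthAxis, calibrate, default_axis

QUALITY_LABELS = (0, 1, 2, 3)
QUALITY_NAMES = {0: "fresh", 1: "newly damaged", 2: "2 h after damage", 3: "4 h after damage"}

# class-dependent spectral parameters (index = quality code)
_RED_EDGE_LOSS_PER_CLASS = 0.06      # fractional red-edge amplitude loss per class
_BROWNING_DEPTH_PER_CLASS = 0.025    # browning trough depth per class, reflectance
_DAMAGE_DEPTH = (0.0, 0.06, 0.10, 0.14)  # in-blob depression at 746 nm per class


@dataclass(frozen=True)
class ClassSpectrumModel:
    """Reflectance curve of one quality class plus its in-damage offset."""

    class_label: int
    axis: WavelengthAxis
    base_curve: np.ndarray           # reflectance in [0, 1], one value per band
    peak_components: tuple[tuple[float, float, float], ...]  # (center nm, width nm, amplitude)
    damage_shift: np.ndarray         # additive offset applied inside damage regions

    def curve_at(self, nm: float) -> float:
        return float(self.base_curve[self.axis.nearest_index(nm)])


@dataclass(frozen=True)
class SceneSpec:
    """Geometry and noise levels of one synthetic capture."""

    height: int = 120
    width: int = 120
    fruit_center: tuple[float, float] = (60.0, 60.0)
    fruit_radius: float = 45.0
    damage_center: tuple[float, float] = (52.0, 68.0)
    damage_radius: float = 12.0
    boundary_roughness: float = 0.25
    noise_std_inside: float = 0.004      # reflectance units, 450-850 nm
    noise_std_outside: float = 0.012     # reflectance units, below 450 / above 850 nm
    texture_std: float = 0.010           # spatially correlated pericarp texture
    texture_corr_len: float = 3.0        # pixels
    illum_std: float = 0.01              # smooth multiplicative illumination field
    illum_corr_len: float = 25.0         # pixels
    ref_noise_std: float = 0.002         # reference-frame noise, fraction of gain
    background_reflectance: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_std_outside < self.noise_std_inside:
            raise ValueError("noise outside 450-850 nm must be >= noise inside")
        if self.fruit_radius <= 0 or self.damage_radius <= 0:
            raise ValueError("radii must be positive")


@dataclass
class SyntheticSample:
    """One rendered capture with its references and ground truth."""

    raw: RawCube
    refs: ReferenceFrames
    label: int
    fruit_mask: np.ndarray
    damage_mask: np.ndarray
    seed: int
    model: ClassSpectrumModel
    scene: SceneSpec
    sample_id: str = ""

    def calibrated(self) -> ReflectanceCube:
        return calibrate(self.raw, self.refs)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def make_class_spectrum(
    class_label: int,
    axis: WavelengthAxis | None = None,
    seed: int = 0,
    jitter: bool = True,
) -> ClassSpectrumModel:
    """Build the (seeded) reflectance model of one quality class.

    The same seed with different labels shares the random shape jitter, so
    class curves stay strictly ordered sample by sample.  With ``jitter=False``
    the population-mean curve is returned.
    """
    if class_label not in QUALITY_LABELS:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {QUALITY_LABELS}")
    if axis is None:
        axis = default_axis()
    lam = axis.values
    rng = np.random.default_rng(seed)
    if jitter:
        edge_amp_f = rng.normal(1.0, 0.01)
        bump_amp_f = rng.normal(1.0, 0.03)
        edge_center = 685.0 + rng.normal(0.0, 1.5)
        bump_center = 560.0 + rng.normal(0.0, 1.5)
        floor_f = rng.normal(1.0, 0.02)
    else:
        edge_amp_f = bump_amp_f = floor_f = 1.0
        edge_center, bump_center = 685.0, 560.0

    c = class_label
    edge_amp = 0.55 * (1.0 - _RED_EDGE_LOSS_PER_CLASS * c) * edge_amp_f
    bump_amp = 0.10 * bump_amp_f
    trough_amp = _BROWNING_DEPTH_PER_CLASS * c

    curve = (
        0.08 * floor_f
        + edge_amp * _sigmoid((lam - edge_center) / 18.0)
        + bump_amp * _gauss(lam, bump_center, 25.0)
        - trough_amp * _gauss(lam, 746.0, 55.0)
    )
    curve = np.clip(curve, 0.0, 1.0)

    damage_shift = -_DAMAGE_DEPTH[c] * _gauss(lam, 746.0, 45.0)
    peaks = (
        (bump_center, 25.0, bump_amp),
        (edge_center, 18.0, edge_amp),
        (746.0, 55.0, -trough_amp),
    )
    return ClassSpectrumModel(c, axis, curve, peaks, damage_shift)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian random field with ~corr_len smoothness."""
    noise = rng.standard_normal(shape)
    f = gaussian_filter(noise, sigma=corr_len, mode="reflect")
    s = f.std()
    return (f - f.mean()) / (s if s > 0 else 1.0)


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rough_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    roughness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Disc with a seeded low-order harmonic perturbation of its boundary."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for k in (2, 3, 4):
        pert += rng.normal(0.0, 1.0 / k) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    peak = np.max(np.abs(pert))
    if peak > 0:
        pert = pert / peak
    local_r = radius * (1.0 + roughness * pert)
    return dy**2 + dx**2 <= local_r**2


def render_sample(
    scene: SceneSpec,
    model: ClassSpectrumModel,
    gain: float = 3000.0,
    seed: int = 0,
    sample_id: str = "",
) -> SyntheticSample:
    """Render one raw cube with its reference frames and ground-truth masks.

    Raw counts follow the inverse calibration model
    ``I0 = D + (W - D) * R + noise`` with per-band noise std tripled outside
    450–850 nm; the damage blob (classes 1–3 only) carries the model's
    ``damage_shift`` and doubled texture noise.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    rng = np.random.default_rng(seed)
    shape2d = (scene.height, scene.width)
    lam = model.axis.values
    n_bands = lam.size

    fruit = _disc_mask(shape2d, scene.fruit_center, scene.fruit_radius)
    if model.class_label == 0:
        damage = np.zeros(shape2d, dtype=bool)
    else:
        damage = _rough_blob(shape2d, scene.damage_center, scene.damage_radius,
                             scene.boundary_roughness, rng) & np.ones(shape2d, bool)
        if not np.all(fruit[damage]):
            raise ValueError("damage blob extends outside the fruit disc")
        if not damage.any():
            raise ValueError("damage blob is empty")

    # reflectance field
    refl = np.full((*shape2d, n_bands), scene.background_reflectance, dtype=np.float64)
    refl[fruit] = model.base_curve
    if damage.any():
        refl[damage] += model.damage_shift

    texture = _smooth_field(rng, shape2d, scene.texture_corr_len) * scene.texture_std
    texture = np.where(damage, 2.0 * texture, texture)
    refl[fruit] += texture[fruit, None]

    illum = 1.0 + scene.illum_std * _smooth_field(rng, shape2d, scene.illum_corr_len)
    refl[fruit] *= illum[fruit, None]

    band_std = np.where((lam >= 450.0) & (lam <= 850.0),
                        scene.noise_std_inside, scene.noise_std_outside)
    if np.any(band_std > 0):
        refl = refl + rng.standard_normal(refl.shape) * band_std
    refl = np.clip(refl, 0.0, 1.2)

    # reference frames: smooth white near the gain, dark near 1 % of gain
    white = gain * (1.0 + 0.02 * _smooth_field(rng, shape2d, 20.0))
    dark = 0.01 * gain * (1.0 + 0.05 * _smooth_field(rng, shape2d, 20.0))
    if scene.ref_noise_std > 0:
        white = white + rng.standard_normal(shape2d) * scene.ref_noise_std * gain
        dark = dark + rng.standard_normal(shape2d) * 0.2 * scene.ref_noise_std * gain
    white = np.maximum(white, dark + 0.5 * gain)[..., None]  # keep W - D well away from 0
    dark = dark[..., None]

    counts = dark + (white - dark) * refl
    counts = np.maximum(counts, 0.0).astype(np.float32)

    raw = RawCube(counts, model.axis, source=sample_id or None)
    refs = ReferenceFrames(white.astype(np.float32), dark.astype(np.float32))
    return SyntheticSample(raw, refs, model.class_label, fruit, damage, seed, model, scene,
                           sample_id=sample_id)


def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def iter_dataset(
    n_per_class: int,
    scene: SceneSpec | None = None,
    seed: int = 0,
    gain: float = 3000.0,
    axis: WavelengthAxis | None = None,
    id_prefix: str = "sample",
):
    """Yield ``4 * n_per_class`` samples, labels interleaved 0,1,2,3,0,1,...

    Per-sample seeds derive deterministically from the master seed; each
    sample gets a jittered spectral model and a jittered damage-blob
    placement, emulating fruit-to-fruit variation within a batch.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if scene is None:
        scene = SceneSpec()
    if axis is None:
        axis = default_axis()
    seeds = _child_seeds(seed, 4 * n_per_class)
    k = 0
    for i in range(n_per_class):
        for label in QUALITY_LABELS:
            s = seeds[k]
            jitter_rng = np.random.default_rng(s + 1)
            # jitter damage placement while keeping the blob inside the fruit
            dc = np.array(scene.damage_center) + jitter_rng.uniform(-6, 6, size=2)
            dr = scene.damage_radius * jitter_rng.uniform(0.85, 1.15)
            max_off = scene.fruit_radius - dr * (1 + scene.boundary_roughness) - 1
            off = dc - np.array(scene.fruit_center)
            dist = np.hypot(*off)
            if dist > max_off:
                dc = np.array(scene.fruit_center) + off * (max_off / dist)
            sample_scene = replace(scene, damage_center=(float(dc[0]), float(dc[1])),
                                   damage_radius=float(dr))
            model = make_class_spectrum(label, axis, seed=s)
            yield render_sample(sample_scene, model, gain=gain, seed=s,
                                sample_id=f"{id_prefix}_{k:03d}_c{label}")
            k += 1


def generate_dataset(
    n_per_class: int,
    scene: SceneSpec | None = None,
    seed: int = 0,
    gain: float = 3000.0,
    axis: WavelengthAxis | None = None,
    id_prefix: str = "sample",
) -> list[SyntheticSample]:
    """Materialized :func:`iter_dataset` (use the iterator for large runs)."""
    return list(iter_dataset(n_per_class, scene, seed, gain, axis, id_prefix))


def write_dataset(samples: list[SyntheticSample], out_dir) -> "Path":
    """Write samples as ENVI cube pairs plus masks (PNG) and a manifest CSV.

    Raw cubes are quantized to unsigned 16-bit on disk; reference frames are
    stored as float32 ENVI-style pairs with a two-entry dummy axis removed —
    here simply as .npy arrays next to the cube.  Returns the manifest path.
    """
    from pathlib import Path

    import imageio.v3 as iio
    import pandas as pd

    from .hsi_io import write_envi

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        sid = s.sample_id or f"sample_{len(rows):03d}"
        img_path, _ = write_envi(s.raw, out_dir / sid)
        white_path = out_dir / f"{sid}_white.npy"
        dark_path = out_dir / f"{sid}_dark.npy"
        np.save(white_path, s.refs.white)
        np.save(dark_path, s.refs.dark)
        fruit_path = out_dir / f"{sid}_fruit.png"
        damage_path = out_dir / f"{sid}_damage.png"
        iio.imwrite(fruit_path, (s.fruit_mask * 255).astype(np.uint8))
        iio.imwrite(damage_path, (s.damage_mask * 255).astype(np.uint8))
        rows.append({"sample_id": sid, "label": s.label, "seed": s.seed,
                     "cube": img_path.name, "white": white_path.name,
                     "dark": dark_path.name, "fruit_mask": fruit_path.name,
                     "damage_mask": damage_path.name})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
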