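"""End-to-end orchestration of the litchi grading workflow.

Stage order mirrors the acquisition-to-report procedure: simulate raw cubes,
calibrate to reflectance, extract and preprocess ROI spectra, PLS-DA on the
spectra, image PCA and characteristic-band selection, damage segmentation on
a single-band or PC-score image, GLCM texture features over the segmented
fruit, LS-SVM classification, and table-style reports.  Every stage draws its
randomness from a child of the master seed, so a rerun with the same
configuration reproduces the report files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bands as bands_mod
from . import glcm as glcm_mod
from . import lssvm as lssvm_mod
from . import plsda as plsda_mod
from . import prep, synth
from .hsi_io import ReflectanceCube, default_axis, trim_bands
from .report import ClassReport
from .segment import mask_iou, segment_damage


@dataclass
class PipelineConfig:
    # synthetic data
    n_per_class: int = 30              # modeling pool: 4 x 30 = 120 samples
    n_external_per_class: int = 20     # external validation: 4 x 20 = 80
    gain: float = 3000.0
    scene: dict = field(default_factory=dict)   # SceneSpec overrides
    # spectra
    trim_lo_nm: float = 450.0
    trim_hi_nm: float = 850.0
    roi_size: int = 50
    sg_window: int = 11
    sg_polyorder: int = 2
    prep_mode: str = "both"
    # PLS-DA
    calibration_fraction: float = 0.6
    max_latent: int = 10
    # PCA / band selection
    n_pc: int = 7
    selection_pc: int = 3
    max_pixels: int = 50_000
    smooth_window: int = 7
    min_prominence_frac: float = 0.05
    # segmentation + texture
    image_source: str = "band:725"     # or "pc:<k>"
    glcm_levels: int = 64
    glcm_distance: int = 1
    # LS-SVM
    gamma_grid: tuple = lssvm_mod.DEFAULT_GAMMA_GRID
    sigma2_grid: tuple = lssvm_mod.DEFAULT_SIGMA2_GRID
    cv_folds: int = 5
    # bookkeeping
    seed: int = 42
    out_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gamma_grid", "sigma2_grid"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def scene_spec(self) -> synth.SceneSpec:
        return synth.SceneSpec(**self.scene)

    def to_snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["gamma_grid"] = list(self.gamma_grid)
        d["sigma2_grid"] = list(self.sigma2_grid)
        return d


@dataclass
class RunManifest:
    stages: list
    config: dict
    version: str
    seed: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"stages": self.stages, "config": self.config,
             "version": self.version, "seed": self.seed}, indent=2))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seeds(master: int, n: int) -> list[int]:
    return [int(s) % (2**31) for s in np.random.SeedSequence(master).generate_state(n)]


def _gray_for(cube: ReflectanceCube, cfg: PipelineConfig,
              pca: bands_mod.PCAResult | None) -> np.ndarray:
    kind, _, arg = cfg.image_source.partition(":")
    if kind == "band":
        return bands_mod.band_image(cube, float(arg))
    if kind == "pc":
        if pca is None:
            raise ValueError("PC-score image requested before PCA stage")
        return bands_mod.score_image(cube, pca, int(arg))
    raise ValueError(f"unknown image source {cfg.image_source!r}")


def _process_set(cfg: PipelineConfig, n_per_class: int, seed: int,
                 pca: bands_mod.PCAResult | None, seg_seed: int, id_prefix: str):
    """Stream one sample set: spectra, segmentation stats and GLCM features."""
    spectra, feat_rows, seg_rows = [], [], []
    scene = cfg.scene_spec()
    for sample in synth.iter_dataset(n_per_class, scene, seed=seed, gain=cfg.gain,
                                     id_prefix=id_prefix):
        cube = sample.calibrated()
        roi = prep.roi_for_sample(sample.fruit_mask, sample.damage_mask, cfg.roi_size)
        spec = prep.extract_roi_mean(trim_bands(cube, cfg.trim_lo_nm, cfg.trim_hi_nm),
                                     roi, sample.sample_id, sample.label)
        spectra.append(prep.preprocess(spec, cfg.sg_window, cfg.sg_polyorder, cfg.prep_mode))

        gray = _gray_for(cube, cfg, pca)
        seg = segment_damage(gray, seed=seg_seed)
        iou = mask_iou(seg.damage_mask, sample.damage_mask)
        seg_rows.append({
            "sample_id": sample.sample_id, "label": sample.label,
            "fruit_area": int(seg.fruit_mask.sum()),
            "damage_area": int(seg.damage_mask.sum()),
            "damage_fraction": round(seg.damage_fraction, 6),
            "iou_vs_truth": round(iou, 6),
        })
        feats = glcm_mod.region_features(gray, seg.fruit_mask, cfg.glcm_levels,
                                         cfg.glcm_distance)
        row = {"sample_id": sample.sample_id, "label": sample.label}
        row.update({name: float(v) for name, v in
                    zip(glcm_mod.FEATURE_NAMES, feats.as_array())})
        feat_rows.append(row)
    return spectra, pd.DataFrame(feat_rows), pd.DataFrame(seg_rows)


def run_all(cfg: PipelineConfig) -> RunManifest:
    """Execute the full workflow; returns a manifest of outputs and hashes."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    (seed_model, seed_ext, seed_split, seed_lssvm,
     seed_pca, seed_seg, seed_repr) = _child_seeds(cfg.seed, 7)

    def record(name: str, t0: float, paths: list[Path]) -> None:
        stages.append({"stage": name,
                       "outputs": {str(p): _sha256(p) for p in paths},
                       "wall_time_s": round(time.perf_counter() - t0, 3)})

    # --- image PCA on one representative cube per class ------------------
    t0 = time.perf_counter()
    repr_samples = synth.generate_dataset(1, cfg.scene_spec(), seed=seed_repr,
                                          gain=cfg.gain, id_prefix="repr")
    repr_cubes = [s.calibrated() for s in repr_samples]
    pixels = bands_mod.assemble_pixels(repr_cubes, [s.fruit_mask for s in repr_samples],
                                       max_pixels=cfg.max_pixels, seed=seed_pca)
    pca = bands_mod.image_pca(pixels, n_pc=cfg.n_pc)
    selected = bands_mod.pc_loading_extrema(pca, cfg.selection_pc, cfg.smooth_window,
                                            cfg.min_prominence_frac)
    contrib_path = out / "pca_contributions.csv"
    pca.contribution_frame().to_csv(contrib_path, index=False, float_format="%.6g")
    loadings_path = out / "pca_loadings.csv"
    pca.loading_frame().to_csv(loadings_path, index=False, float_format="%.9g")
    bands_path = selected.to_json(out / "characteristic_bands.json")
    del repr_samples, repr_cubes, pixels
    record("band_selection", t0, [contrib_path, loadings_path, bands_path])

    # --- simulate + calibrate + extract + segment + texture --------------
    t0 = time.perf_counter()
    spectra, feats, segs = _process_set(cfg, cfg.n_per_class, seed_model, pca,
                                        seed_seg, "model")
    spectra_ext, feats_ext, segs_ext = _process_set(cfg, cfg.n_external_per_class,
                                                    seed_ext, pca, seed_seg, "ext")
    table = prep.build_table(spectra)
    table_ext = prep.build_table(spectra_ext)
    spectra_path = prep.table_to_csv(table, out / "spectra_model.csv")
    spectra_ext_path = prep.table_to_csv(table_ext, out / "spectra_external.csv")
    feats_path = out / "features_model.csv"
    feats.to_csv(feats_path, index=False, float_format="%.9g")
    feats_ext_path = out / "features_external.csv"
    feats_ext.to_csv(feats_ext_path, index=False, float_format="%.9g")
    seg_path = out / "segmentation.csv"
    pd.concat([segs, segs_ext]).to_csv(seg_path, index=False)
    record("extract_segment_texture", t0,
           [spectra_path, spectra_ext_path, feats_path, feats_ext_path, seg_path])

    # --- PLS-DA on spectra ------------------------------------------------
    t0 = time.perf_counter()
    tr, va = plsda_mod.stratified_split(table.y, cfg.calibration_fraction, seed_split)
    cal = prep.SpectrumTable(table.X[tr], table.y[tr], table.axis,
                             [table.sample_ids[i] for i in tr])
    n_lv = plsda_mod.choose_n_latent(cal, cfg.max_latent)
    model = plsda_mod.fit_pls(cal, n_lv)
    plsda_val = plsda_mod.evaluate(plsda_mod.predict_class(model, table.X[va]), table.y[va])
    plsda_ext = plsda_mod.evaluate(plsda_mod.predict_class(model, table_ext.X), table_ext.y)
    model_path = model.to_json(out / "plsda_model.json")
    val_path = plsda_val.to_csv(out / "plsda_validation.csv")
    ext_path = plsda_ext.to_csv(out / "plsda_external.csv")
    record("plsda", t0, [model_path, val_path, ext_path])

    # --- LS-SVM on texture features --------------------------------------
    t0 = time.perf_counter()
    fX = feats[list(glcm_mod.FEATURE_NAMES)].to_numpy(float)
    fy = feats["label"].to_numpy(int)
    ftr, fva = plsda_mod.stratified_split(fy, cfg.calibration_fraction, seed_split)
    ensemble = lssvm_mod.fit_multiclass(fX[ftr], fy[ftr], cfg.gamma_grid,
                                        cfg.sigma2_grid, cfg.cv_folds, seed_lssvm)
    lssvm_val = lssvm_mod.confusion_and_accuracy(ensemble.predict(fX[fva]), fy[fva])
    fX_ext = feats_ext[list(glcm_mod.FEATURE_NAMES)].to_numpy(float)
    lssvm_ext = lssvm_mod.confusion_and_accuracy(ensemble.predict(fX_ext),
                                                 feats_ext["label"].to_numpy(int))
    ens_path = lssvm_mod.ensemble_to_json(ensemble, out / "lssvm_model.json")
    lval_path = lssvm_val.to_csv(out / "lssvm_validation.csv")
    lext_path = lssvm_ext.to_csv(out / "lssvm_external.csv")
    record("lssvm", t0, [ens_path, lval_path, lext_path])

    # --- summary ----------------------------------------------------------
    t0 = time.perf_counter()
    summary_path = out / "summary.txt"
    summary_path.write_text(render_summary(plsda_val, plsda_ext, lssvm_val, lssvm_ext,
                                           n_lv, selected.wavelengths.tolist()))
    manifest = RunManifest(stages, cfg.to_snapshot(), _version(), cfg.seed)
    record("summary", t0, [summary_path])
    manifest.to_json(out / "manifest.json")
    return manifest


def render_summary(plsda_val: ClassReport, plsda_ext: ClassReport,
                   lssvm_val: ClassReport, lssvm_ext: ClassReport,
                   n_latent: int, wavelengths: list[float]) -> str:
    """Human-readable rendering of both classifier reports."""
    def block(title: str, rep: ClassReport) -> str:
        lines = [title, rep.to_frame().to_string(),
                 f"mean per-type recall:    {rep.mean_recall:.2f} %",
                 f"mean per-type precision: {rep.mean_precision:.2f} %",
                 f"average accuracy:        {rep.mean_accuracy:.2f} %", ""]
        return "\n".join(lines)

    parts = [
        "Litchi hyperspectral grading - pipeline summary",
        "=" * 48,
        f"PLS-DA latent variables (LOO-CV): {n_latent}",
        f"characteristic wavelengths (nm): {', '.join(f'{w:g}' for w in wavelengths)}",
        "",
        block("PLS-DA validation set (spectra)", plsda_val),
        block("PLS-DA external set (spectra)", plsda_ext),
        block("LS-SVM validation set (GLCM texture)", lssvm_val),
        block("LS-SVM external set (GLCM texture)", lssvm_ext),
    ]
    return "\n".join(parts)


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("litchi-hsi")
    except Exception:
        return "unknown"
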