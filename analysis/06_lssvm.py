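"""Stage 6 — LS-SVM grading from texture features.

One-vs-one least-squares SVMs on the 7-dimensional GLCM descriptor,
hyperparameters picked by stratified 5-fold cross-validation on the
72-sample training split; confusion-matrix reports for the 48-sample
validation set and the 80-sample external set.
"""

from pathlib import Path

import pandas as pd

from litchi_hsi import lssvm, plsda
from litchi_hsi.glcm import FEATURE_NAMES
from litchi_hsi.pipeline import PipelineConfig, _child_seeds

RESULTS = Path("results")


def main() -> None:
    cfg = PipelineConfig()
    seeds = _child_seeds(cfg.seed, 7)
    feats = pd.read_csv(RESULTS / "features_model.csv")
    feats_ext = pd.read_csv(RESULTS / "features_external.csv")
    X = feats[list(FEATURE_NAMES)].to_numpy(float)
    y = feats["label"].to_numpy(int)

    tr, va = plsda.stratified_split(y, cfg.calibration_fraction, seeds[2])
    ens = lssvm.fit_multiclass(X[tr], y[tr], cfg.gamma_grid, cfg.sigma2_grid,
                               cfg.cv_folds, seeds[3])
    lssvm.ensemble_to_json(ens, RESULTS / "lssvm_model.json")

    rep_val = lssvm.confusion_and_accuracy(ens.predict(X[va]), y[va])
    rep_ext = lssvm.confusion_and_accuracy(
        ens.predict(feats_ext[list(FEATURE_NAMES)].to_numpy(float)),
        feats_ext["label"].to_numpy(int))
    rep_val.to_csv(RESULTS / "lssvm_validation.csv")
    rep_ext.to_csv(RESULTS / "lssvm_external.csv")

    print(f"chosen gamma={ens.gamma:g}, sigma^2={ens.sigma2:g} "
          f"(CV accuracy {100 * (ens.cv_accuracy or 0):.1f} %)")
    print(f"validation average accuracy: {rep_val.mean_accuracy:.2f} %")
    print(f"external   average accuracy: {rep_ext.mean_accuracy:.2f} %")
    print(rep_val.to_frame().to_string())


if __name__ == "__main__":
    main()
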