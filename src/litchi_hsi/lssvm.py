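"""Least-squares SVM classification of texture features.

An LS-SVM replaces the SVM's inequality constraints with equality constraints
and squared-error loss, so training a binary machine reduces to one linear
system in the bias b and support values alpha::

    [ 0    1^T          ] [ b     ]   [ 0 ]
    [ 1    K + I/gamma  ] [ alpha ] = [ y ]

with kernel matrix K and labels y in {-1, +1}.  Four quality classes are
handled one-vs-one (6 binary machines, majority vote, ties to the smallest
code); the regularization gamma and RBF width sigma^2 are picked jointly by
stratified k-fold cross-validated accuracy.  Features are standardized with
training statistics inside each binary machine — GLCM features span orders
of magnitude and an unstandardized RBF kernel degenerates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .report import CLASS_CODES, ClassReport, classification_report

DEFAULT_GAMMA_GRID = (1.0, 10.0, 100.0, 1e3, 1e4)
DEFAULT_SIGMA2_GRID = (0.1, 1.0, 10.0, 100.0)


def _rbf(A: np.ndarray, B: np.ndarray, sigma2: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma2))


@dataclass
class LSSVMBinaryModel:
    alpha: np.ndarray
    b: float
    gamma: float
    kernel: str                    # 'rbf' or 'linear'
    sigma2: float
    X_train: np.ndarray            # standardized training features
    feat_mean: np.ndarray
    feat_std: np.ndarray
    residual: float                # relative residual of the KKT system

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X) - self.feat_mean) / self.feat_std
        if self.kernel == "rbf":
            K = _rbf(Xs, self.X_train, self.sigma2)
        else:
            K = Xs @ self.X_train.T
        return K @ self.alpha + self.b


def fit_binary(
    features: np.ndarray,
    labels: np.ndarray,
    gamma: float = 100.0,
    kernel: str = "rbf",
    sigma2: float = 1.0,
) -> LSSVMBinaryModel:
    """Solve the LS-SVM dual system for one +/-1 problem."""
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels, dtype=np.float64).ravel()
    if X.shape[0] != y.size:
        raise ValueError("feature rows must match labels")
    if not set(np.unique(y)) <= {-1.0, 1.0} or np.unique(y).size < 2:
        raise ValueError("labels must contain both -1 and +1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if kernel not in ("rbf", "linear"):
        raise ValueError(f"unknown kernel {kernel!r}")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    Xs = (X - mean) / std

    n = Xs.shape[0]
    K = _rbf(Xs, Xs, sigma2) if kernel == "rbf" else Xs @ Xs.T
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], y])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular LS-SVM system") from exc
    residual = float(np.linalg.norm(A @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return LSSVMBinaryModel(sol[1:], float(sol[0]), gamma, kernel, sigma2,
                            Xs, mean, std, residual)


@dataclass
class MulticlassEnsemble:
    models: dict                   # (code_lo, code_hi) -> LSSVMBinaryModel
    codes: tuple[int, ...]
    gamma: float
    sigma2: float
    kernel: str
    cv_accuracy: float | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain NaN or infinity")
        first = next(iter(self.models.values()))
        if X.shape[1] != first.feat_mean.size:
            raise ValueError(f"expected {first.feat_mean.size}-dim features")
        votes = np.zeros((X.shape[0], len(self.codes)), dtype=int)
        code_pos = {c: k for k, c in enumerate(self.codes)}
        for (lo, hi), model in self.models.items():
            dec = model.decision_value(X)
            votes[dec >= 0, code_pos[lo]] += 1   # +1 side encodes the lower code
            votes[dec < 0, code_pos[hi]] += 1
        # argmax returns the first (smallest) code on vote ties
        return np.array([self.codes[int(np.argmax(v))] for v in votes])

    def predict_one(self, feature_vector: np.ndarray) -> int:
        return int(self.predict(np.atleast_2d(feature_vector))[0])


def _fit_ovo(X: np.ndarray, y: np.ndarray, gamma: float, sigma2: float,
             kernel: str, codes: tuple[int, ...]) -> dict:
    models = {}
    for lo, hi in combinations(codes, 2):
        sel = np.isin(y, (lo, hi))
        yy = np.where(y[sel] == lo, 1.0, -1.0)
        models[(lo, hi)] = fit_binary(X[sel], yy, gamma=gamma, kernel=kernel, sigma2=sigma2)
    return models


def fit_multiclass(
    features: np.ndarray,
    labels: np.ndarray,
    gamma_grid=DEFAULT_GAMMA_GRID,
    sigma2_grid=DEFAULT_SIGMA2_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
) -> MulticlassEnsemble:
    """One-vs-one LS-SVM ensemble with (gamma, sigma^2) grid search.

    The grid is searched by stratified ``cv_folds``-fold CV multiclass
    accuracy on the training data; ties keep the first (smallest) pair.  With
    a single-point grid no CV is run.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(labels, dtype=int).ravel()
    codes = tuple(int(c) for c in np.unique(y))
    if len(codes) < 2:
        raise ValueError("need at least two classes")
    gamma_grid = tuple(gamma_grid)
    sigma2_grid = tuple(sigma2_grid) if kernel == "rbf" else (1.0,)
    if not gamma_grid or not sigma2_grid:
        raise ValueError("empty hyperparameter grid")

    if len(gamma_grid) * len(sigma2_grid) == 1:
        best_gamma, best_sigma2, best_acc = gamma_grid[0], sigma2_grid[0], None
    else:
        folds = min(cv_folds, int(np.min(np.bincount(np.searchsorted(codes, y)))))
        folds = max(folds, 2)
        # canonical sample order so the chosen grid point does not depend on
        # how the caller happened to order the training rows
        canon = np.lexsort(np.vstack([X.T, y]))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = [(canon[tr], canon[te]) for tr, te in skf.split(X[canon], y[canon])]
        best_gamma = best_sigma2 = None
        best_acc = -1.0
        for gamma in gamma_grid:
            for sigma2 in sigma2_grid:
                correct = total = 0
                for tr, te in splits:
                    if np.unique(y[tr]).size < len(codes):
                        continue
                    models = _fit_ovo(X[tr], y[tr], gamma, sigma2, kernel, codes)
                    ens = MulticlassEnsemble(models, codes, gamma, sigma2, kernel)
                    correct += int((ens.predict(X[te]) == y[te]).sum())
                    total += te.size
                acc = correct / total if total else 0.0
                if acc > best_acc:
                    best_acc, best_gamma, best_sigma2 = acc, gamma, sigma2
    models = _fit_ovo(X, y, best_gamma, best_sigma2, kernel, codes)
    return MulticlassEnsemble(models, codes, best_gamma, best_sigma2, kernel,
                              cv_accuracy=best_acc)


def confusion_and_accuracy(preds, truth) -> ClassReport:
    """Table-4-style report: 4x4 counts, per-class and average accuracy."""
    return classification_report(preds, truth)


def ensemble_to_json(ensemble: MulticlassEnsemble, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "codes": list(ensemble.codes), "gamma": ensemble.gamma,
        "sigma2": ensemble.sigma2, "kernel": ensemble.kernel,
        "models": {
            f"{lo}-{hi}": {
                "alpha": m.alpha.tolist(), "b": m.b,
                "X_train": m.X_train.tolist(),
                "feat_mean": m.feat_mean.tolist(), "feat_std": m.feat_std.tolist(),
            }
            for (lo, hi), m in ensemble.models.items()
        },
    }
    path.write_text(json.dumps(payload))
    return path


def ensemble_from_json(path: str | Path) -> MulticlassEnsemble:
    d = json.loads(Path(path).read_text())
    models = {}
    for key, m in d["models"].items():
        lo, hi = (int(x) for x in key.split("-"))
        models[(lo, hi)] = LSSVMBinaryModel(
            np.array(m["alpha"]), float(m["b"]), d["gamma"], d["kernel"], d["sigma2"],
            np.array(m["X_train"]), np.array(m["feat_mean"]), np.array(m["feat_std"]),
            residual=0.0,
        )
    return MulticlassEnsemble(models, tuple(d["codes"]), d["gamma"], d["sigma2"], d["kernel"])
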