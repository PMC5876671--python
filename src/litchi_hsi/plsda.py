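"""PLS-DA discrimination of the four litchi quality classes.

Partial least squares regression against a single ordinal response coded
0 (fresh), 1 (newly damaged), 2 (2 h after damage), 3 (4 h after damage),
fit by sequential NIPALS extraction on mean-centered data.  A continuous
prediction is mapped to the nearest class code.  The number of latent
variables is chosen by leave-one-out cross-validation of the coded-response
RMSE.

With one response the NIPALS weight step is closed-form (no inner iteration):
for each component, w = X'y / ||X'y||, t = Xw, p = X't/(t't), q = y't/(t't),
then X and y are deflated by the rank-one score contribution.  The assembled
coefficient vector B = W (P'W)^-1 q predicts in one matrix product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .prep import MeanSpectrum, SpectrumTable
from .report import CLASS_CODES, ClassReport, classification_report


@dataclass
class PLSDAModel:
    x_mean: np.ndarray     # band centering vector
    y_mean: float          # response centering scalar
    W: np.ndarray          # weights, bands x LV, columns unit-norm
    P: np.ndarray          # X-loadings, bands x LV
    q: np.ndarray          # y-loadings, LV
    B: np.ndarray          # regression coefficients, bands
    n_latent: int
    codes: tuple[int, ...] = CLASS_CODES
    scores: np.ndarray | None = None   # training scores, samples x LV

    def predict_value(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.B.size:
            raise ValueError(f"expected {self.B.size} bands, got {X.shape[1]}")
        return (X - self.x_mean) @ self.B + self.y_mean

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "x_mean": self.x_mean.tolist(), "y_mean": self.y_mean,
            "W": self.W.tolist(), "P": self.P.tolist(), "q": self.q.tolist(),
            "B": self.B.tolist(), "n_latent": self.n_latent, "codes": list(self.codes),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSDAModel":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["x_mean"]), float(d["y_mean"]), np.array(d["W"]),
                   np.array(d["P"]), np.array(d["q"]), np.array(d["B"]),
                   int(d["n_latent"]), tuple(d["codes"]))


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_latent: int):
    """Sequential PLS1 extraction on centered X, y. Returns W, P, q, T."""
    n, p = X.shape
    Xd = X.copy()
    yd = y.copy()
    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    q = np.zeros(n_latent)
    T = np.zeros((n, n_latent))
    for k in range(n_latent):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            # remaining covariance exhausted; truncate
            return W[:, :k], P[:, :k], q[:k], T[:, :k]
        w /= norm
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            return W[:, :k], P[:, :k], q[:k], T[:, :k]
        p_k = Xd.T @ t / tt
        q_k = float(yd @ t / tt)
        Xd -= np.outer(t, p_k)
        yd = yd - q_k * t
        W[:, k], P[:, k], q[k], T[:, k] = w, p_k, q_k, t
    return W, P, q, T


def fit_pls(table: SpectrumTable, n_latent: int) -> PLSDAModel:
    """Fit the PLS1 model on mean-centered spectra and coded response."""
    X = table.X
    y = table.y.astype(float)
    n, p = X.shape
    if n_latent < 1 or n_latent > min(n - 1, p):
        raise ValueError(f"n_latent must be in [1, {min(n - 1, p)}]")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("zero-variance spectra")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, T = _nipals_pls1(X - x_mean, y - y_mean, n_latent)
    if W.shape[1] == 0:
        raise ValueError("no extractable covariance between X and y")
    B = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(x_mean, y_mean, W, P, q, B, W.shape[1], scores=T)


def predict_class(model: PLSDAModel, spectrum: MeanSpectrum | np.ndarray) -> int | np.ndarray:
    """Nearest-code assignment; exact midpoints resolve to the lower code."""
    values = spectrum.values if isinstance(spectrum, MeanSpectrum) else np.asarray(spectrum, float)
    single = values.ndim == 1
    yhat = model.predict_value(np.atleast_2d(values))
    codes = np.asarray(model.codes, dtype=float)
    # argmin returns the first (lowest) code on distance ties
    assigned = np.array([model.codes[int(np.argmin(np.abs(codes - v)))] for v in yhat])
    return int(assigned[0]) if single else assigned


def choose_n_latent(table: SpectrumTable, max_latent: int = 10) -> int:
    """Leave-one-out CV over 1..max_latent; returns the RMSE-minimizing count.

    Each fold is fit once at the largest feasible dimension and evaluated at
    every truncation, so the search costs one NIPALS pass per left-out sample.
    Ties resolve to the smallest count.
    """
    n, p = table.X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out selection")
    kmax = min(max_latent, n - 2, p)
    y = table.y.astype(float)
    sq_err = np.zeros(kmax)
    counts = np.zeros(kmax)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = table.X[mask], y[mask]
        x_mean = X_tr.mean(axis=0)
        y_mean = y_tr.mean()
        W, P, q, _ = _nipals_pls1(X_tr - x_mean, y_tr - y_mean, kmax)
        got = W.shape[1]
        x0 = table.X[i] - x_mean
        for k in range(1, got + 1):
            Bk = W[:, :k] @ np.linalg.solve(P[:, :k].T @ W[:, :k], q[:k])
            pred = float(x0 @ Bk) + y_mean
            sq_err[k - 1] += (pred - y[i]) ** 2
            counts[k - 1] += 1
    valid = counts > 0
    rmse = np.full(kmax, np.inf)
    rmse[valid] = np.sqrt(sq_err[valid] / counts[valid])
    return int(np.argmin(rmse)) + 1   # argmin takes the smallest index on ties


def evaluate(preds, truth) -> ClassReport:
    """Confusion matrix with per-class recall/precision and unweighted means."""
    return classification_report(preds, truth)


def stratified_split(y, frac: float = 0.6, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified partition; every class lands in both parts.

    Returns (calibration indices, validation indices), each sorted.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        n_cal = int(round(frac * idx.size))
        n_cal = min(max(n_cal, 1), idx.size - 1)
        train.extend(idx[:n_cal])
        test.extend(idx[n_cal:])
    return np.sort(train), np.sort(test)
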