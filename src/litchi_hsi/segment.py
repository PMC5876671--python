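"""Fruit localization and damage segmentation on single-band / PC-score images.

Pipeline (per image): histogram equalization, Otsu thresholding to separate
the bright fruit from the dark background, connected-component filtering,
Roberts-operator edge detection for boundary delineation, then fuzzy c-means
(c = 2) on the fruit-interior intensities of the *original* gray image.  The
lower-mean cluster is the damage candidate — bruised pericarp appears dark in
the red/NIR band images — and is accepted only if the two cluster centers are
clearly separated and the candidate stays a minority of the fruit area, so an
intact fruit with unimodal intensities yields an empty damage mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def _check_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D gray image")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    return img.astype(np.int64)


def equalize_hist(image: np.ndarray) -> np.ndarray:
    """Classic cumulative-histogram equalization to [0, 255].

    The mapping is monotone non-decreasing; a constant image is returned
    unchanged.
    """
    img = _check_gray(image)
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(np.float64)
    nonzero = np.flatnonzero(hist)
    if nonzero.size <= 1:
        return img.astype(np.uint8)
    cdf_min = cdf[nonzero[0]]
    n = img.size
    mapping = np.round(255.0 * (cdf - cdf_min) / (n - cdf_min)).astype(np.uint8)
    return mapping[img]


def otsu_threshold(values: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's threshold over the 256-bin histogram.

    Accepts a gray image or a flat vector of masked gray values.  Returns
    ``(t, mask)`` where ``t`` maximizes the between-class variance of the
    split ``value <= t`` vs ``value > t`` (ties resolve to the lowest t) and
    ``mask = values > t``.
    """
    flat = np.asarray(values).astype(np.int64).ravel()
    if flat.size == 0:
        raise ValueError("no values supplied")
    if flat.min() < 0 or flat.max() > 255:
        raise ValueError("gray values must lie in [0, 255]")
    if np.all(flat == flat[0]):
        raise ValueError("constant image has no Otsu threshold")

    hist = np.bincount(flat, minlength=256).astype(np.float64)
    n = flat.size
    omega = np.cumsum(hist)                      # pixels with value <= t
    mu = np.cumsum(hist * np.arange(256))        # intensity mass <= t
    mu_total = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        numer = (mu_total * omega - mu * n) ** 2
        denom = omega * (n - omega)
        sigma_b = np.where(denom > 0, numer / denom, -np.inf)
    t = int(np.argmax(sigma_b[:-1]))             # argmax takes the lowest tie
    mask = np.asarray(values) > t
    return t, mask


def robert_edges(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Roberts cross-gradient magnitude and its Otsu-binarized edge mask.

    ``Gx = I(r, c) - I(r+1, c+1)`` and ``Gy = I(r, c+1) - I(r+1, c)`` on each
    2 x 2 stencil; the magnitude image keeps the source shape with zeros on
    the last row/column where the stencil does not fit.
    """
    img = _check_gray(image).astype(np.float64)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2 x 2")
    gx = img[:-1, :-1] - img[1:, 1:]
    gy = img[:-1, 1:] - img[1:, :-1]
    magnitude = np.zeros_like(img)
    magnitude[:-1, :-1] = np.hypot(gx, gy)

    scaled = np.round(255.0 * magnitude / max(magnitude.max(), 1e-12)).astype(np.int64)
    if np.all(scaled == scaled.flat[0]):
        edge_mask = np.zeros(img.shape, dtype=bool)
    else:
        t, _ = otsu_threshold(scaled.ravel())
        edge_mask = scaled > t
    return magnitude, edge_mask


@dataclass
class FCMState:
    centers: np.ndarray            # c x d
    memberships: np.ndarray        # n x c, rows sum to 1
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def fuzzy_cmeans(
    values: np.ndarray,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
    init: str = "percentile",
) -> FCMState:
    """Standard fuzzy c-means on feature vectors.

    Alternates membership updates ``u_ik ∝ d_ik^(-2/(m-1))`` and
    membership^m-weighted center updates until the objective change drops
    below ``tol``.  For 1-D data the default initialization places centers at
    evenly spaced percentiles (deterministic); otherwise centers start at
    seeded random data points.  Points coinciding with a center get crisp
    membership.
    """
    X = np.asarray(values, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if n < c:
        raise ValueError(f"need at least {c} points")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if np.allclose(X, X[0]):
        raise ValueError("all points identical; clustering is degenerate")

    rng = np.random.default_rng(seed)
    if init == "percentile" and d == 1:
        qs = np.linspace(25, 75, c) if c > 1 else np.array([50.0])
        centers = np.percentile(X, qs, axis=0)
    else:
        centers = X[rng.choice(n, size=c, replace=False)]
    if np.unique(centers, axis=0).shape[0] < c:  # collapse guard
        centers = centers + rng.normal(0, 1e-6 * (X.std() + 1e-12), centers.shape)

    exponent = 2.0 / (m - 1.0)
    trace = []
    prev_obj = np.inf
    converged = False
    U = np.zeros((n, c))
    for it in range(1, max_iter + 1):
        dist2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = dist2 < 1e-24
        U = np.zeros((n, c))
        any_zero = zero.any(axis=1)
        if any_zero.any():
            U[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        ok = ~any_zero
        if ok.any():
            # u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)) = d_ik^(-2/(m-1)) normalized
            w = dist2[ok] ** (-exponent / 2.0)
            U[ok] = w / w.sum(axis=1, keepdims=True)
        Um = U**m
        obj = float((Um * dist2).sum())
        trace.append(obj)
        centers = (Um.T @ X) / np.maximum(Um.sum(axis=0)[:, None], 1e-300)
        if abs(prev_obj - obj) < tol:
            converged = True
            break
        prev_obj = obj
    return FCMState(centers, U, np.array(trace), len(trace), converged)


@dataclass
class SegmentationResult:
    fruit_mask: np.ndarray
    damage_mask: np.ndarray
    edge_mask: np.ndarray
    threshold: int
    fcm: FCMState | None
    equalized: np.ndarray

    @property
    def damage_fraction(self) -> float:
        fruit_area = int(self.fruit_mask.sum())
        return float(self.damage_mask.sum()) / fruit_area if fruit_area else 0.0


def _components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Union of 8-connected components with at least ``min_area`` pixels."""
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    if keep.size == 0:
        keep = np.array([int(np.argmax(areas)) + 1])
    return np.isin(labels, keep)


def segment_damage(
    image: np.ndarray,
    fruit_mask: np.ndarray | None = None,
    seed: int = 0,
    min_fruit_area: int = 500,
    min_center_sep: float = 8.0,
    max_damage_frac: float = 0.25,
    min_damage_area: int = 20,
    fuzzifier: float = 2.0,
) -> SegmentationResult:
    """Locate the fruit and its damaged region in one gray image.

    When ``fruit_mask`` is supplied it constrains the Otsu foreground;
    otherwise the fruit is found from scratch.  Damage is the lower-mean FCM
    cluster of fruit-interior intensities, accepted only when the cluster
    centers are at least ``min_center_sep`` gray levels apart and the
    candidate covers at most ``max_damage_frac`` of the fruit.
    """
    img = _check_gray(image)
    eq = equalize_hist(img)
    try:
        t, fg = otsu_threshold(eq)
    except ValueError as exc:
        raise ValueError("no fruit found: image has no separable foreground") from exc
    if fruit_mask is not None:
        fg = fg & np.asarray(fruit_mask, dtype=bool)
    fruit = _components(fg, min_fruit_area)
    if not fruit.any() or fruit.sum() < min_fruit_area:
        raise ValueError("no fruit found: Otsu foreground is empty or too small")
    # dark bruises fall below the fruit/background threshold and punch holes
    fruit = ndimage.binary_fill_holes(fruit)

    _, edge_mask = robert_edges(eq)

    # interior: stay off the fruit boundary before clustering intensities
    interior = ndimage.binary_erosion(fruit, iterations=2)
    if interior.sum() < min_damage_area:
        interior = fruit
    vals = img[interior].astype(np.float64)

    damage = np.zeros_like(fruit)
    fcm = None
    if np.ptp(vals) > 0:
        fcm = fuzzy_cmeans(vals, c=2, m=fuzzifier, seed=seed)
        centers = fcm.centers.ravel()
        low = int(np.argmin(centers))
        sep = float(abs(centers[1] - centers[0]))
        candidate = np.zeros_like(fruit)
        candidate[interior] = fcm.hard_labels() == low
        frac = candidate.sum() / max(fruit.sum(), 1)
        if sep >= min_center_sep and frac <= max_damage_frac:
            damage = _components(candidate, min_damage_area) & candidate
            if damage.sum() < min_damage_area:
                damage = np.zeros_like(fruit)
    return SegmentationResult(fruit, damage, edge_mask, t, fcm, eq)


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
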