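"""Per-pixel cell-boundary probability maps.

The colocalization statistic consumes a probability map: for every pixel, the
posterior probability that it belongs to a cell wall.  Two interchangeable
producers are provided behind the same :class:`ProbabilityMap` contract:

* a supervised pixel classifier (multiscale filter-bank features + random
  forest), the self-contained equivalent of interactive pixel-classification
  tools used for this kind of boundary segmentation;
* a deterministic multiscale ridge filter fallback that needs no training
  labels.

Features per smoothing scale: Gaussian-smoothed intensity, gradient
magnitude, Laplacian, and the largest Hessian eigenvalue, plus the raw
intensity once — ``4 * n_scales + 1`` features, in that documented order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from sklearn.ensemble import RandomForestClassifier
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import sato

DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.5, 5.0)

__all__ = [
    "ProbabilityMap",
    "PixelTrainingSet",
    "PixelClassifier",
    "DEFAULT_SCALES",
    "compute_feature_stack",
    "build_training_set",
    "sample_training_from_mask",
    "train_pixel_classifier",
    "predict_probability_map",
    "ridge_probability_map",
]


@dataclass
class ProbabilityMap:
    """Per-pixel boundary probability on the source image grid."""

    values: np.ndarray
    source_id: str = ""
    method: str = "ridge_filter"   # or "trained_classifier"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("probability map must be 2-D")
        if not np.isfinite(v).all():
            raise ValueError("probability map contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """32-bit float TIFF plus a JSON provenance sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        sidecar = {"source_id": self.source_id, "method": self.method}
        sidecar.update(extra or {})
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ProbabilityMap":
        path = Path(path)
        values = tifffile.imread(path).astype(float)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(values, source_id=meta.get("source_id", ""),
                   method=meta.get("method", "ridge_filter"))


@dataclass
class PixelTrainingSet:
    """Labelled per-pixel feature vectors (labels: 1 = boundary, 0 = not)."""

    feature_matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    scales: tuple[float, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if len(np.unique(labels)) < 2:
            raise ValueError("training set must contain both classes "
                             "(boundary and not_boundary)")
        if len(labels) != len(self.feature_matrix):
            raise ValueError("labels and feature_matrix length mismatch")


@dataclass
class PixelClassifier:
    """Serializable classifier honouring the predict_probability contract."""

    model: RandomForestClassifier
    scales: tuple[float, ...]
    feature_names: list[str]

    def predict_probability(self, features: np.ndarray) -> np.ndarray:
        if features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature-configuration mismatch: classifier expects "
                f"{len(self.feature_names)} features, got {features.shape[1]}"
            )
        idx = int(np.where(self.model.classes_ == 1)[0][0])
        return self.model.predict_proba(features)[:, idx]


def feature_names_for_scales(scales) -> list[str]:
    names = ["intensity"]
    for s in scales:
        names += [f"gaussian_s{s}", f"gradmag_s{s}", f"laplacian_s{s}",
                  f"hessian_max_eig_s{s}"]
    return names


def compute_feature_stack(image: np.ndarray,
                          scales=DEFAULT_SCALES) -> tuple[np.ndarray, list[str]]:
    """Multiscale filter-bank features, shape (H, W, 4*n_scales + 1).

    Order per scale: smoothed intensity, gradient magnitude, Laplacian,
    largest Hessian eigenvalue; raw intensity is feature 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite pixels")
    if len(scales) < 1:
        raise ValueError("need at least one scale")
    feats = [img]
    for s in scales:
        smoothed = ndi.gaussian_filter(img, s)
        gy = ndi.gaussian_filter(img, s, order=(1, 0))
        gx = ndi.gaussian_filter(img, s, order=(0, 1))
        gradmag = np.hypot(gy, gx)
        # the discrete LoG kernel carries a small DC pedestal (its weights
        # do not sum exactly to zero); subtract the operator's response to
        # a constant so flat images give exactly-zero features
        m = 2 * int(np.ceil(4 * s)) + 3
        lap_dc = ndi.gaussian_laplace(np.ones((m, m)), s)[m // 2, m // 2]
        lap = ndi.gaussian_laplace(img, s) - lap_dc * smoothed
        H = hessian_matrix(img, sigma=s, order="rc", mode="reflect",
                           use_gaussian_derivatives=True)
        eig = hessian_matrix_eigvals(H)[0]   # largest eigenvalue
        feats += [smoothed, gradmag, lap, eig]
    stack = np.stack(feats, axis=-1)
    return stack, feature_names_for_scales(scales)


def build_training_set(image: np.ndarray,
                       boundary_coords: np.ndarray,
                       background_coords: np.ndarray,
                       scales=DEFAULT_SCALES) -> PixelTrainingSet:
    """Training set from labelled pixel coordinates (rows of (y, x))."""
    stack, names = compute_feature_stack(image, scales)
    b = np.asarray(boundary_coords, dtype=int)
    g = np.asarray(background_coords, dtype=int)
    X = np.vstack([stack[b[:, 0], b[:, 1]], stack[g[:, 0], g[:, 1]]])
    y = np.concatenate([np.ones(len(b), dtype=int), np.zeros(len(g), dtype=int)])
    return PixelTrainingSet(X, y, names, tuple(scales))


def sample_training_from_mask(image: np.ndarray, boundary_mask: np.ndarray,
                              n_per_class: int = 2000, rng_seed: int = 0,
                              scales=DEFAULT_SCALES,
                              exclusion_px: float = 2.0) -> PixelTrainingSet:
    """Sample labelled pixels from a ground-truth wall mask (synthetic use).

    Pixels within ``exclusion_px`` of the wall (but not on it) are excluded
    from the negative class — a "don't-care" band, as when boundary labels
    are painted with a brush: emitters line up *near* walls, so the
    classifier must not be trained to score the immediate wall
    neighbourhood as hard zero.
    """
    rng = np.random.default_rng(rng_seed)
    dist = ndi.distance_transform_edt(~boundary_mask)
    pos = np.argwhere(boundary_mask)
    neg = np.argwhere(dist > exclusion_px)
    pos = pos[rng.choice(len(pos), min(n_per_class, len(pos)), replace=False)]
    neg = neg[rng.choice(len(neg), min(n_per_class, len(neg)), replace=False)]
    return build_training_set(image, pos, neg, scales)


def train_pixel_classifier(train: PixelTrainingSet,
                           n_estimators: int = 50,
                           max_depth: int | None = 12,
                           rng_seed: int = 0) -> PixelClassifier:
    """Fit the random-forest pixel classifier (seeded, single-threaded)."""
    model = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        random_state=rng_seed, n_jobs=1)
    model.fit(train.feature_matrix, train.labels)
    return PixelClassifier(model, tuple(train.scales), list(train.feature_names))


def predict_probability_map(image: np.ndarray, classifier: PixelClassifier,
                            source_id: str = "") -> ProbabilityMap:
    """Boundary probability for every pixel of ``image``."""
    stack, names = compute_feature_stack(image, classifier.scales)
    if names != classifier.feature_names:
        raise ValueError("feature-configuration mismatch between image "
                         "features and classifier")
    h, w, f = stack.shape
    probs = classifier.predict_probability(stack.reshape(-1, f)).reshape(h, w)
    return ProbabilityMap(probs, source_id=source_id, method="trained_classifier")


def ridge_probability_map(image: np.ndarray, scales=DEFAULT_SCALES,
                          source_id: str = "") -> ProbabilityMap:
    """Training-free fallback: multiscale bright-ridge strength in [0, 1].

    Sato tubeness over ``scales``, then robust normalization: clip to the
    1st–99th percentile and rescale linearly.  A constant image maps to all
    zeros (no ridges), by contract.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if np.ptp(img) == 0:
        return ProbabilityMap(np.zeros_like(img), source_id=source_id,
                              method="ridge_filter")
    resp = sato(img, sigmas=list(scales), black_ridges=False, mode="reflect")
    lo, hi = np.percentile(resp, [1.0, 99.0])
    if hi <= lo:
        return ProbabilityMap(np.zeros_like(img), source_id=source_id,
                              method="ridge_filter")
    vals = np.clip((resp - lo) / (hi - lo), 0.0, 1.0)
    return ProbabilityMap(vals, source_id=source_id, method="ridge_filter")
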