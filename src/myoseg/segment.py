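"""Two-stage random-forest pixel classification of fiber boundaries.

A primary classifier is trained on sparse boundary / intra-fiber pixel
annotations of the preprocessed laminin channel; an iterative classifier makes
the same two-way call but is trained on the grayscale probability maps the
primary classifier emits, sharpening the boundary/interior separation.

Probability maps follow the dark-boundary convention:
``value = round(255 * (1 - P(boundary)))``, so confident boundary pixels are 0
and confident intra-fiber pixels are 255.

Per-pixel features (fixed, documented order): raw intensity; Gaussian blur at
each sigma; Sobel gradient magnitude at each sigma; Hessian eigenvalues
(larger, then smaller) at each sigma; difference of Gaussians for each
adjacent sigma pair; grayscale maximum filter at each radius.  The default
sigma ladder {1, 2, 4, 8, 16} px with maximum-filter radii {1, 2} yields a
27-plane stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import filters as skfilters
from sklearn.ensemble import RandomForestClassifier

from .io import AnnotationMask, MyosegError

BOUNDARY_CLASS = 1
INTERIOR_CLASS = 2


@dataclass
class FeatureConfig:
    gaussian_sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    include_sobel: bool = True
    include_hessian: bool = True
    include_dog: bool = True
    include_maximum: bool = True
    max_filter_radii: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        s = self.gaussian_sigmas
        if any(x <= 0 for x in s) or any(a >= b for a, b in zip(s, s[1:])):
            raise MyosegError("gaussian_sigmas must be positive and strictly increasing")
        if not self.feature_names():
            raise MyosegError("at least one feature must be enabled")

    def feature_names(self) -> list[str]:
        names = ["raw"]
        names += [f"gauss_s{s:g}" for s in self.gaussian_sigmas]
        if self.include_sobel:
            names += [f"sobel_s{s:g}" for s in self.gaussian_sigmas]
        if self.include_hessian:
            for s in self.gaussian_sigmas:
                names += [f"hess_hi_s{s:g}", f"hess_lo_s{s:g}"]
        if self.include_dog:
            names += [
                f"dog_s{a:g}_{b:g}"
                for a, b in zip(self.gaussian_sigmas, self.gaussian_sigmas[1:])
            ]
        if self.include_maximum:
            names += [f"max_r{r}" for r in self.max_filter_radii]
        return names

    @property
    def n_features(self) -> int:
        return len(self.feature_names())


def extract_features(plane: np.ndarray, fc: FeatureConfig) -> np.ndarray:
    """Per-pixel feature stack, shape ``(H, W, n_features)`` float32."""
    x = plane.astype(np.float32)
    planes: list[np.ndarray] = [x]
    blurred = {s: ndimage.gaussian_filter(x, s) for s in fc.gaussian_sigmas}
    planes += [blurred[s] for s in fc.gaussian_sigmas]
    if fc.include_sobel:
        planes += [skfilters.sobel(blurred[s]) for s in fc.gaussian_sigmas]
    if fc.include_hessian:
        for s in fc.gaussian_sigmas:
            H = skfeature.hessian_matrix(x, sigma=s, order="rc", mode="nearest",
                                         use_gaussian_derivatives=False)
            hi, lo = skfeature.hessian_matrix_eigvals(H)
            planes += [hi, lo]
    if fc.include_dog:
        planes += [
            blurred[a] - blurred[b]
            for a, b in zip(fc.gaussian_sigmas, fc.gaussian_sigmas[1:])
        ]
    if fc.include_maximum:
        planes += [
            ndimage.maximum_filter(x, size=2 * r + 1) for r in fc.max_filter_radii
        ]
    return np.stack(planes, axis=-1).astype(np.float32)


@dataclass
class ProbMap:
    """8-bit boundary probability rendering (dark = boundary)."""

    values: np.ndarray  # uint8

    def __post_init__(self) -> None:
        if self.values.dtype != np.uint8:
            raise MyosegError("ProbMap values must be uint8")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def p_boundary(self) -> np.ndarray:
        return 1.0 - self.values.astype(np.float64) / 255.0


def _to_probmap(p_boundary: np.ndarray) -> ProbMap:
    vals = np.floor(255.0 * (1.0 - p_boundary) + 0.5).astype(np.uint8)
    return ProbMap(values=vals)


@dataclass
class PixelClassifier:
    """A fitted two-class random forest plus its feature recipe and domain tag.

    ``domain`` records what the classifier was trained on: ``"raw"`` for
    preprocessed laminin planes (the primary classifier) or ``"probmap"`` for
    probability maps (the iterative classifier); the tag makes the two-stage
    contract checkable at call time.
    """

    feature_config: FeatureConfig
    domain: str = "raw"
    n_trees: int = 200
    seed: int = 0
    forest: RandomForestClassifier | None = field(default=None, repr=False)

    @property
    def is_trained(self) -> bool:
        return self.forest is not None and hasattr(self.forest, "classes_")

    def _boundary_column(self) -> int:
        return int(np.where(self.forest.classes_ == BOUNDARY_CLASS)[0][0])

    def predict_p_boundary(self, features: np.ndarray) -> np.ndarray:
        if not self.is_trained:
            raise MyosegError("classifier has not been trained")
        h, w, f = features.shape
        proba = self.forest.predict_proba(features.reshape(-1, f))
        return proba[:, self._boundary_column()].reshape(h, w)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise MyosegError(f"{path} is not a PixelClassifier archive")
        return obj


def train_classifier(
    images: list[np.ndarray],
    masks: list[AnnotationMask],
    fc: FeatureConfig | None = None,
    *,
    domain: str = "raw",
    n_trees: int = 200,
    seed: int = 0,
) -> PixelClassifier:
    """Fit a boundary/intra-fiber random forest on annotated pixels.

    Deterministic for a fixed seed.  Raises if the annotations do not contain
    both classes (a minimum of two classes is required).
    """
    if domain not in ("raw", "probmap"):
        raise MyosegError(f"domain must be 'raw' or 'probmap', got {domain!r}")
    fc = fc or FeatureConfig()
    X_parts, y_parts = [], []
    for img, mask in zip(images, masks):
        if img.shape != mask.labels.shape:
            raise MyosegError("image and annotation mask shapes differ")
        feats = extract_features(img, fc)
        sel = mask.labels > 0
        X_parts.append(feats[sel])
        y_parts.append(mask.labels[sel])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if not ((y == BOUNDARY_CLASS).any() and (y == INTERIOR_CLASS).any()):
        raise MyosegError(
            "annotations must contain both classes (boundary and intra-fiber)"
        )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return PixelClassifier(feature_config=fc, domain=domain, n_trees=n_trees,
                           seed=seed, forest=forest)


def classify(plane: np.ndarray, clf: PixelClassifier) -> ProbMap:
    """Apply the primary (raw-domain) classifier to a preprocessed plane."""
    if clf.domain != "raw":
        raise MyosegError(
            "classify() needs a raw-domain classifier; got domain "
            f"{clf.domain!r} (use iterative_classify for probmap classifiers)"
        )
    feats = extract_features(plane, clf.feature_config)
    return _to_probmap(clf.predict_p_boundary(feats))


def iterative_classify(pm: ProbMap, clf2: PixelClassifier) -> ProbMap:
    """Apply the iterative (probmap-domain) classifier to a probability map."""
    if clf2.domain != "probmap":
        raise MyosegError(
            "iterative_classify() needs a probmap-domain classifier; got "
            f"domain {clf2.domain!r}"
        )
    feats = extract_features(pm.values, clf2.feature_config)
    return _to_probmap(clf2.predict_p_boundary(feats))


def classify_tiles(tiles, clf: PixelClassifier, clf2: PixelClassifier | None = None):
    """Classify each tile independently (primary, then optional iterative pass).

    Returns a TileSet-shaped list of uint8 probmap tiles in the input order.
    """
    out = []
    for tile in tiles:
        pm = classify(tile, clf)
        if clf2 is not None:
            pm = iterative_classify(pm, clf2)
        out.append(pm.values)
    return out


def classify_tiled_plane(plane: np.ndarray, offsets, tile_shapes,
                         clf: PixelClassifier,
                         clf2: PixelClassifier | None = None,
                         margin: int = 32) -> list[np.ndarray]:
    """Classify disjoint tiles of ``plane`` with a context margin.

    Each tile is classified on a window enlarged by ``margin`` pixels of real
    image context (clipped at the image border) and only the tile core is
    kept, so the larger-support features (Gaussian ladder up to sigma 16) see
    the same neighbourhood they would in a whole-image pass and the stitched
    probability map carries no seam artifacts.  Tiles themselves stay
    disjoint.
    """
    h, w = plane.shape
    out = []
    for (r, c), (th, tw) in zip(offsets, tile_shapes):
        r0, c0 = max(r - margin, 0), max(c - margin, 0)
        r1, c1 = min(r + th + margin, h), min(c + tw + margin, w)
        window = plane[r0:r1, c0:c1]
        pm = classify(window, clf)
        if clf2 is not None:
            pm = iterative_classify(pm, clf2)
        out.append(pm.values[r - r0:r - r0 + th, c - c0:c - c0 + tw])
    return out
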