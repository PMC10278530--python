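"""Pixel classification of pseudo-IHC images into tumor vs stroma.

Two routes produce a :class:`~tsrzone.core.TumorMask`:

* a deterministic one — optical-density transform, H-DAB color
  deconvolution and a threshold on the DAB channel — suited to phantoms
  with well-separated hues, and
* a trainable one — a multiscale filter-bank feature stack fed to a
  random-forest ensemble fit on user scribbles, with iterative label
  refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian
from sklearn.ensemble import RandomForestClassifier

from .core import CalibratedImage, TumorMask

#: Unit-norm H-DAB optical-density basis (hematoxylin, DAB, residual),
#: Ruifrok-style constants.  Rows are stains, columns RGB channels.
DEFAULT_STAIN_VECTORS = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.268, 0.570, 0.776],
        [0.0, 0.0, 0.0],  # residual filled below
    ]
)
DEFAULT_STAIN_VECTORS[0] /= np.linalg.norm(DEFAULT_STAIN_VECTORS[0])
DEFAULT_STAIN_VECTORS[1] /= np.linalg.norm(DEFAULT_STAIN_VECTORS[1])
_res = np.cross(DEFAULT_STAIN_VECTORS[0], DEFAULT_STAIN_VECTORS[1])
DEFAULT_STAIN_VECTORS[2] = _res / np.linalg.norm(_res)
DEFAULT_STAIN_VECTORS.setflags(write=False)

#: DAB concentration threshold separating the phantom hues.
DEFAULT_DAB_THRESHOLD = 0.5

#: Default smoothing scales (um) for the trainable route.
DEFAULT_FEATURE_SCALES_UM = (0.5, 1.0, 2.0, 4.0)

LABEL_TUMOR = 1
LABEL_STROMA = 2


def rgb_to_optical_density(image: CalibratedImage) -> np.ndarray:
    """Per-channel optical density, OD = -log10((I + 1) / 256).

    OD is >= 0 for intensities in [0, 255] and monotone decreasing in
    intensity, so bright (unstained) pixels map near zero.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    if pixels.min() < 0 or pixels.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return -np.log10((pixels + 1.0) / 256.0)


def deconvolve_hdab(
    od_raster: np.ndarray, stain_vectors: np.ndarray | None = None
) -> np.ndarray:
    """Unmix an OD raster into per-stain concentrations.

    Parameters
    ----------
    od_raster : ndarray, shape (..., 3)
    stain_vectors : ndarray, shape (3, 3), optional
        Rows = (hematoxylin, DAB, residual) unit OD vectors.  Defaults to
        the standard H-DAB basis.

    Returns
    -------
    ndarray of the same shape; last axis indexes (H, DAB, residual)
    concentrations.  ``concentrations @ stain_vectors`` reconstructs the
    input OD exactly (up to float rounding).
    """
    basis = DEFAULT_STAIN_VECTORS if stain_vectors is None else np.asarray(stain_vectors, float)
    if basis.shape != (3, 3):
        raise ValueError("stain_vectors must be 3x3")
    try:
        inv = np.linalg.inv(basis)
    except np.linalg.LinAlgError as exc:
        raise ValueError("stain basis is singular") from exc
    return np.asarray(od_raster, float) @ inv


def threshold_classify(
    dab_raster: np.ndarray, threshold: float, mpp: float
) -> TumorMask:
    """Binary tumor mask from a DAB concentration raster."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return TumorMask((np.asarray(dab_raster) >= threshold).astype(np.uint8), mpp)


def _feature_stack(image: CalibratedImage, scales_um: tuple[float, ...]) -> np.ndarray:
    """(H, W, F) filter-bank features: raw OD plus Gaussian-smoothed OD and
    OD gradient magnitude at each physical scale."""
    od = rgb_to_optical_density(image)
    feats = [od]
    for scale in scales_um:
        sigma_px = max(scale / image.mpp, 0.1)
        smoothed = gaussian(od, sigma=sigma_px, channel_axis=-1, preserve_range=True)
        gy, gx = np.gradient(smoothed, axis=(0, 1))
        feats.append(smoothed)
        feats.append(np.hypot(gy, gx))
    return np.concatenate(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Filter-bank + random-forest tumor/stroma pixel classifier.

    Scribble rasters use 0 = unlabeled, 1 = tumor, 2 = stroma.
    """

    feature_scales: tuple[float, ...] = DEFAULT_FEATURE_SCALES_UM
    seed: int = 0
    trained_model: RandomForestClassifier | None = None
    class_labels: tuple[str, str] = ("tumor", "stroma")
    _train_X: np.ndarray | None = field(default=None, repr=False)
    _train_y: np.ndarray | None = field(default=None, repr=False)

    @property
    def trained(self) -> bool:
        return self.trained_model is not None

    def _fit(self) -> None:
        model = RandomForestClassifier(
            n_estimators=50, random_state=self.seed, n_jobs=1
        )
        model.fit(self._train_X, self._train_y)
        self.trained_model = model


def _scribble_samples(
    image: CalibratedImage, scribbles: np.ndarray, scales: tuple[float, ...]
) -> tuple[np.ndarray, np.ndarray]:
    scribbles = np.asarray(scribbles)
    if scribbles.shape != image.shape:
        raise ValueError("scribble raster must match image shape")
    for lab, name in ((LABEL_TUMOR, "tumor"), (LABEL_STROMA, "stroma")):
        if not (scribbles == lab).any():
            raise ValueError(f"no scribble pixels for class '{name}'")
    feats = _feature_stack(image, scales)
    sel = scribbles > 0
    return feats[sel], scribbles[sel]


def train_pixel_classifier(
    image: CalibratedImage,
    labeled_scribbles: np.ndarray,
    feature_scales_um: tuple[float, ...] = DEFAULT_FEATURE_SCALES_UM,
    seed: int = 0,
) -> PixelClassifier:
    """Fit the ensemble on scribble pixels; deterministic given ``seed``."""
    X, y = _scribble_samples(image, labeled_scribbles, feature_scales_um)
    clf = PixelClassifier(feature_scales=tuple(feature_scales_um), seed=seed)
    clf._train_X, clf._train_y = X, y
    clf._fit()
    return clf


def refine_classifier(
    classifier: PixelClassifier,
    image: CalibratedImage,
    additional_scribbles: np.ndarray,
) -> PixelClassifier:
    """Retrain on the union of previous and newly added labels.

    An empty addition (all zeros) leaves predictions unchanged: the model
    is refit on identical data with the same seed.
    """
    if not classifier.trained:
        raise ValueError("classifier must be trained before refinement")
    additional_scribbles = np.asarray(additional_scribbles)
    if additional_scribbles.shape != image.shape:
        raise ValueError("scribble raster must match image shape")
    refined = PixelClassifier(
        feature_scales=classifier.feature_scales, seed=classifier.seed
    )
    if (additional_scribbles > 0).any():
        feats = _feature_stack(image, classifier.feature_scales)
        sel = additional_scribbles > 0
        refined._train_X = np.vstack([classifier._train_X, feats[sel]])
        refined._train_y = np.concatenate(
            [classifier._train_y, additional_scribbles[sel]]
        )
    else:
        refined._train_X = classifier._train_X
        refined._train_y = classifier._train_y
    refined._fit()
    return refined


def predict_mask(classifier: PixelClassifier, image: CalibratedImage) -> TumorMask:
    """One tumor/stroma label per pixel; no randomness at inference."""
    if not classifier.trained:
        raise ValueError("classifier is not trained")
    feats = _feature_stack(image, classifier.feature_scales)
    flat = feats.reshape(-1, feats.shape[-1])
    pred = classifier.trained_model.predict(flat).reshape(image.shape)
    return TumorMask((pred == LABEL_TUMOR).astype(np.uint8), image.mpp)


def segment_by_threshold(
    image: CalibratedImage,
    threshold: float = DEFAULT_DAB_THRESHOLD,
    stain_vectors: np.ndarray | None = None,
) -> TumorMask:
    """Deterministic pipeline: OD -> H-DAB unmixing -> DAB threshold."""
    od = rgb_to_optical_density(image)
    conc = deconvolve_hdab(od, stain_vectors)
    return threshold_classify(conc[..., 1], threshold, image.mpp)
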