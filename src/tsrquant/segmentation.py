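"""Pixel classification of H&E patches into epithelium / stroma / background.

The default segmenter is a deterministic stain-deconvolution rule: RGB
intensities are converted to optical densities (Beer-Lambert), unmixed
against the standard hematoxylin/eosin/residual stain matrix, and each
tissue pixel is labeled epithelium where the smoothed
hematoxylin-minus-eosin concentration exceeds a threshold, stroma
otherwise; low-total-OD pixels are background.  A small pluggable backend
registry lets any patch-level model (including trainable ones) drive the
same tiling pipeline through :func:`segment_slide`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from skimage import filters, morphology

from .labels import LABEL_EPITHELIUM, LABEL_STROMA
from .tiling import Patch, PatchGrid, ROIMask, extract_patches, stitch

__all__ = [
    "StainModel",
    "SegmenterBackend",
    "StainRuleBackend",
    "OracleBackend",
    "PixelModelBackend",
    "od_transform",
    "stain_deconvolve",
    "classify_pixels",
    "segment_slide",
    "BACKENDS",
    "get_backend",
]

# Standard H&E(+residual) optical-density stain vectors (rows), unit-norm.
HE_STAIN_MATRIX = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.072, 0.990, 0.105],  # eosin
        [0.268, 0.570, 0.776],  # residual
    ]
)
HE_STAIN_MATRIX = HE_STAIN_MATRIX / np.linalg.norm(HE_STAIN_MATRIX, axis=1, keepdims=True)


@dataclass(frozen=True)
class StainModel:
    """Parameters of the stain-rule pixel classifier.

    ``background_od_threshold`` separates glass/near-white pixels (total
    OD below it) from tissue; ``epithelium_rule_threshold`` is the cutoff
    on the smoothed hematoxylin-minus-eosin concentration above which a
    tissue pixel is called epithelium (ties and below go to stroma, the
    majority class in desmoplastic tumors); the default sits midway
    between the smoothed scores of pure hematoxylin- and eosin-dominant
    tissue so class boundaries are recovered without bias; ``morphology_radius`` is the
    opening radius in pixels used to remove single-pixel specks, and also
    the sigma of the Gaussian smoothing of the dominance score.
    """

    stain_matrix: np.ndarray = None  # type: ignore[assignment]
    background_od_threshold: float = 0.15
    epithelium_rule_threshold: float = 0.20
    morphology_radius: int = 2

    def __post_init__(self) -> None:
        matrix = HE_STAIN_MATRIX if self.stain_matrix is None else np.asarray(self.stain_matrix, float)
        if matrix.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if abs(np.linalg.det(matrix)) < 1e-8:
            raise ValueError("stain matrix is singular")
        norms = np.linalg.norm(matrix, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must be unit-norm")
        object.__setattr__(self, "stain_matrix", matrix)
        if self.background_od_threshold <= 0 or self.epithelium_rule_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.morphology_radius < 0:
            raise ValueError("morphology_radius must be >= 0")


def od_transform(rgb_patch: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB patch to optical densities.

    ``OD = -log10((I + 1) / 256)`` per channel, so pure white maps to 0
    and darker pixels to larger OD.
    """
    rgb_patch = np.asarray(rgb_patch)
    if rgb_patch.ndim != 3 or rgb_patch.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if rgb_patch.dtype != np.uint8 and (rgb_patch.min() < 0 or rgb_patch.max() > 255):
        raise ValueError("expected 8-bit intensities in [0, 255]")
    return -np.log10((rgb_patch.astype(np.float64) + 1.0) / 256.0)


def stain_deconvolve(
    od_patch: np.ndarray, stain_matrix: np.ndarray = HE_STAIN_MATRIX
) -> tuple[np.ndarray, float]:
    """Unmix per-pixel OD into per-stain concentration channels.

    Solves ``OD = C @ M`` for concentrations ``C`` (rows of ``M`` are the
    stain OD vectors).  Negative concentrations are clipped to zero;
    the returned residual is the maximum absolute remixing error of the
    *unclipped* solution (machine-precision for an invertible matrix).
    """
    stain_matrix = np.asarray(stain_matrix, dtype=float)
    if abs(np.linalg.det(stain_matrix)) < 1e-8:
        raise ValueError("stain matrix is singular")
    od = np.asarray(od_patch, dtype=float)
    raw = od @ np.linalg.inv(stain_matrix)
    residual = float(np.abs(raw @ stain_matrix - od).max(initial=0.0))
    return np.clip(raw, 0.0, None), residual


def classify_pixels(
    rgb_patch: np.ndarray,
    roi: ROIMask | np.ndarray | None = None,
    model: StainModel | None = None,
) -> np.ndarray:
    """Label every pixel of an RGB patch as background/epithelium/stroma.

    Pixels with total OD below the background threshold (or outside the
    ROI, when given) are background.  Remaining tissue pixels are
    epithelium where the Gaussian-smoothed hematoxylin-minus-eosin
    concentration exceeds the rule threshold, stroma otherwise.  A
    morphological opening per tissue class removes specks smaller than
    the morphology radius; pixels opened away from both classes fall
    back to stroma.
    """
    model = model or StainModel()
    od = od_transform(rgb_patch)
    conc, _ = stain_deconvolve(od, model.stain_matrix)
    tissue = od.sum(axis=-1) >= model.background_od_threshold
    if roi is not None:
        roi_mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
        if roi_mask.shape != tissue.shape:
            raise ValueError("ROI shape does not match patch shape")
        tissue &= roi_mask

    score = conc[..., 0] - conc[..., 1]  # hematoxylin minus eosin
    if model.morphology_radius > 0:
        score = filters.gaussian(score, sigma=model.morphology_radius, preserve_range=True)
    epi = tissue & (score > model.epithelium_rule_threshold)
    stroma = tissue & ~epi
    if model.morphology_radius > 0:
        footprint = morphology.disk(model.morphology_radius)
        epi = morphology.opening(epi, footprint) & tissue
        stroma = morphology.opening(stroma, footprint) & tissue

    labels = np.zeros(tissue.shape, dtype=np.uint8)
    labels[tissue] = LABEL_STROMA  # tie-break and opening fallback: stroma
    labels[epi & ~stroma] = LABEL_EPITHELIUM
    return labels


@runtime_checkable
class SegmenterBackend(Protocol):
    """Patch-level segmentation model usable by :func:`segment_slide`.

    ``predict`` receives one :class:`~tsrquant.tiling.Patch` and returns a
    label array of the same spatial shape with values in {0, 1, 2};
    prediction must be deterministic given fixed state and must not use
    neighboring-patch context.  Trainable backends implement ``fit``.
    """

    name: str

    def predict(self, patch: Patch) -> np.ndarray: ...


class StainRuleBackend:
    """Deterministic stain-deconvolution reference segmenter."""

    name = "stain_rule"

    def __init__(self, model: StainModel | None = None) -> None:
        self.model = model or StainModel()

    def predict(self, patch: Patch) -> np.ndarray:
        return classify_pixels(patch.pixels, roi=None, model=self.model)


class OracleBackend:
    """Returns the ground-truth labels for each patch window.

    Test/validation backend: wraps a known truth mask and answers every
    patch by slicing it, so the tiling and stitching path can be checked
    in isolation from any real model.
    """

    name = "oracle"

    def __init__(self, truth_mask: np.ndarray) -> None:
        self.truth_mask = np.asarray(truth_mask)

    def predict(self, patch: Patch) -> np.ndarray:
        r0, c0, r1, c1 = patch.window
        t = patch.pixels.shape[0]
        out = np.zeros((t, t), dtype=np.uint8)
        out[: r1 - r0, : c1 - c0] = self.truth_mask[r0:r1, c0:c1]
        return out


class PixelModelBackend:
    """Trainable per-pixel classifier on RGB features (scikit-learn).

    A shallow decision tree on raw RGB is enough to separate the three
    classes of the synthetic slides; the class exists mainly to exercise
    the trainable half of the backend contract.
    """

    name = "pixel_model"

    def __init__(self, max_depth: int = 6, random_state: int = 0) -> None:
        from sklearn.tree import DecisionTreeClassifier

        self._clf = DecisionTreeClassifier(max_depth=max_depth, random_state=random_state)
        self._fitted = False

    def fit(self, patches: Sequence[Patch], truth_masks: Sequence[np.ndarray]) -> "PixelModelBackend":
        xs, ys = [], []
        for patch, truth in zip(patches, truth_masks):
            valid = patch.valid
            xs.append(patch.pixels[valid].reshape(-1, 3))
            ys.append(np.asarray(truth)[valid].ravel())
        self._clf.fit(np.concatenate(xs), np.concatenate(ys))
        self._fitted = True
        return self

    def predict(self, patch: Patch) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("PixelModelBackend.predict called before fit")
        flat = patch.pixels.reshape(-1, 3)
        return self._clf.predict(flat).astype(np.uint8).reshape(patch.pixels.shape[:2])


BACKENDS: dict[str, Callable[[], SegmenterBackend]] = {
    StainRuleBackend.name: StainRuleBackend,
    PixelModelBackend.name: PixelModelBackend,
}


def get_backend(name: str, **kwargs) -> SegmenterBackend:
    """Instantiate a registered backend by config key."""
    try:
        factory = BACKENDS[name]
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; registered: {sorted(BACKENDS)}") from None
    return factory(**kwargs)


def segment_slide(
    image: np.ndarray,
    roi: ROIMask,
    grid: PatchGrid,
    backend: SegmenterBackend | None = None,
) -> np.ndarray:
    """Segment a whole slide patchwise and stitch back to the canvas.

    Patches are extracted on the grid, predicted independently by the
    backend, and reassembled; the stitched mask is restricted to the ROI
    (non-ROI pixels forced to background).  A backend failure aborts with
    the offending patch window in the error message.
    """
    backend = backend or StainRuleBackend()
    predictions = []
    for patch in extract_patches(image, grid):
        try:
            pred = np.asarray(backend.predict(patch))
        except Exception as exc:
            raise RuntimeError(
                f"backend {backend.name!r} failed on patch window {patch.window}: {exc}"
            ) from exc
        if pred.shape != patch.pixels.shape[:2]:
            raise RuntimeError(
                f"backend {backend.name!r} returned shape {pred.shape} for patch "
                f"window {patch.window}, expected {patch.pixels.shape[:2]}"
            )
        predictions.append(pred)
    return stitch(predictions, grid, roi=roi)
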