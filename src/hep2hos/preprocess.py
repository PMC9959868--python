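"""Contrast adjustment, active-contour segmentation, cropping, rotation.

The segmentation step is a standard edge-based geometric active contour
(level set evolved under an inverse-gradient edge-stopping function with
curvature smoothing and a balloon force), initialized from a bright-seed
threshold.  If the contour collapses, callers may fall back to Otsu
thresholding via :func:`segment_with_fallback` so a batch never
dead-ends on a single difficult image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktransform
from skimage.filters import threshold_otsu
from skimage.segmentation import (
    inverse_gaussian_gradient,
    morphological_geodesic_active_contour,
)

from .synthetic import CellImage


class SegmentationError(RuntimeError):
    """Raised when the evolved contour contains no foreground."""


@dataclass
class SegmentationMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area == 0:
            raise SegmentationError("segmentation produced an empty mask")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class AugmentedSet:
    images: list[CellImage]
    angles: list[float]


def adjust_intensity(
    image: CellImage, low_q: float = 0.02, high_q: float = 0.98
) -> CellImage:
    """Linear contrast stretch mapping the ``low_q``/``high_q`` intensity
    quantiles to 0 and 1, clipping outside.  Constant images pass through
    unchanged."""
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("need 0 <= low_q < high_q <= 1")
    px = image.pixels
    # order-statistic quantiles (no interpolation) make the stretch
    # exactly idempotent: the low/high quantiles of the output are 0 and 1
    lo = np.quantile(px, low_q, method="lower")
    hi = np.quantile(px, high_q, method="higher")
    if hi <= lo:
        return CellImage(px.copy(), image.label, image.intensity_level)
    stretched = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
    return CellImage(stretched, image.label, image.intensity_level)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _postprocess(mask: np.ndarray) -> np.ndarray:
    return ndi.binary_fill_holes(_largest_component(mask))


def segment_gac(
    image: CellImage,
    iterations: int = 100,
    smoothing: int = 2,
    balloon: float = 1.0,
    seed_percentile: float = 75.0,
) -> SegmentationMask:
    """Edge-based geometric-active-contour segmentation.

    The level set evolves on an inverse-Gaussian-gradient edge map with
    curvature ``smoothing`` and a ``balloon`` expansion force, starting
    from the pixels above the ``seed_percentile`` intensity percentile.
    The largest connected component, holes filled, is returned.

    Raises
    ------
    SegmentationError
        If evolution collapses to an empty mask (e.g. an all-zero image).
    """
    px = image.pixels
    thr = np.percentile(px, seed_percentile)
    seed = px > thr
    if not seed.any():
        # flat-topped objects: the percentile can equal the maximum
        seed = (px >= thr) & (px > px.min())
    if px.max() <= 0 or not seed.any():
        raise SegmentationError("no foreground seed found")
    gimage = inverse_gaussian_gradient(px, alpha=100.0, sigma=2.0)
    mask = morphological_geodesic_active_contour(
        gimage,
        num_iter=iterations,
        init_level_set=seed.astype(np.int8),
        smoothing=smoothing,
        balloon=balloon,
    )
    mask = _postprocess(mask.astype(bool))
    if not mask.any():
        raise SegmentationError("active contour collapsed to an empty mask")
    return SegmentationMask(mask)


def segment_otsu(image: CellImage) -> SegmentationMask:
    """Otsu threshold + largest connected component (fallback path)."""
    px = image.pixels
    if px.max() <= px.min():
        raise SegmentationError("constant image cannot be segmented")
    mask = _postprocess(px > threshold_otsu(px))
    if not mask.any():
        raise SegmentationError("Otsu thresholding found no foreground")
    return SegmentationMask(mask)


def segment_with_fallback(image: CellImage, **gac_kwargs) -> SegmentationMask:
    try:
        return segment_gac(image, **gac_kwargs)
    except SegmentationError:
        return segment_otsu(image)


def crop_to_cell(
    image: CellImage, mask: SegmentationMask | np.ndarray, out_size: int = 50
) -> CellImage:
    """Crop the mask's bounding box, pad to square with background 0, and
    rescale to ``out_size`` x ``out_size`` (bilinear)."""
    m = mask.mask if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("cannot crop with an empty mask")
    ys, xs = np.nonzero(m)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    patch = image.pixels[y0:y1, x0:x1]
    h, w = patch.shape
    side = max(h, w)
    square = np.zeros((side, side))
    oy, ox = (side - h) // 2, (side - w) // 2
    square[oy : oy + h, ox : ox + w] = patch
    if side == out_size:
        out = square
    else:
        out = sktransform.resize(
            square, (out_size, out_size), order=1, anti_aliasing=side > out_size
        )
    return CellImage(np.clip(out, 0.0, 1.0), image.label, image.intensity_level)


def rotate_augment(image: CellImage, step_degrees: int = 90) -> AugmentedSet:
    """Rotations at 0, step, 2*step, ..., 360-step about the image centre.

    Right-angle rotations are exact pixel permutations; any other angle
    uses bilinear interpolation with background fill 0.
    """
    if step_degrees <= 0 or 360 % step_degrees != 0:
        raise ValueError("step_degrees must be a positive divisor of 360")
    images, angles = [], []
    for k in range(360 // step_degrees):
        angle = k * step_degrees
        if angle % 90 == 0:
            rotated = np.rot90(image.pixels, k=angle // 90).copy()
        else:
            rotated = sktransform.rotate(
                image.pixels, angle, resize=False, order=1, cval=0.0
            )
        images.append(
            CellImage(np.clip(rotated, 0.0, 1.0), image.label, image.intensity_level)
        )
        angles.append(float(angle))
    return AugmentedSet(images, angles)
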