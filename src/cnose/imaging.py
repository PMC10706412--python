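"""Sensor-array image processing.

Implements the difference-map pipeline for a colorimetric sensor array
photographed before and after exposure to volatile organic compounds:
grayscale conversion, Otsu binarisation, morphological cleanup (area
opening, erosion, size-limited hole filling), reading-order spot
labelling, masking, and the per-pixel absolute colour-difference map
that serves as the VOC fingerprint.

All geometry is 0-based (row, col) with the origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .exceptions import SegmentationError

__all__ = [
    "Phase",
    "SensorImage",
    "SpotLabelMap",
    "DifferenceMap",
    "ImagingParams",
    "to_grayscale",
    "otsu_threshold",
    "area_open",
    "refine_mask",
    "label_spots",
    "apply_mask",
    "difference_map",
    "rescale_for_display",
    "segment_array",
]

#: ITU-R BT.601 luminance weights (R, G, B).
GRAY_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])

#: Default display-rescale input range: a 6-bit window of gray levels.
DISPLAY_RANGE = (3.0, 62.0)


class Phase(str, Enum):
    """Capture phase of a sensor-array photograph."""

    PRE = "pre"
    POST = "post"


@dataclass(frozen=True)
class SensorImage:
    """An RGB photograph of the sensor array.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (H, W, 3)
        8-bit RGB raster.
    phase : Phase
        Whether the capture was taken before or after VOC exposure.
    time_min : float, optional
        Minutes since the start of exposure (for time-lapse frames).
    """

    pixels: np.ndarray
    phase: Phase = Phase.PRE
    time_min: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "phase", Phase(self.phase))
        if self.time_min is not None and self.time_min < 0:
            raise ValueError("time_min must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass(frozen=True)
class SpotLabelMap:
    """Integer raster assigning pixels to spots 1..K in reading order.

    ``labels`` uses 0 for background; ``centroids[k-1]`` is the (row, col)
    centroid of spot k.
    """

    labels: np.ndarray
    centroids: tuple

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int32)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "centroids", tuple(tuple(c) for c in self.centroids))
        present = set(np.unique(lab).tolist()) - {0}
        if present != set(range(1, len(self.centroids) + 1)):
            raise ValueError("labels must be exactly {1..K} with every k present")

    @property
    def n_spots(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class DifferenceMap:
    """Per-pixel, per-channel absolute colour change inside labelled spots."""

    deltas: np.ndarray
    labels: SpotLabelMap

    def __post_init__(self) -> None:
        d = np.asarray(self.deltas, dtype=float)
        if d.shape[:2] != self.labels.labels.shape:
            raise ValueError("deltas shape does not match label map")
        if (d < 0).any():
            raise ValueError("deltas must be nonnegative")
        object.__setattr__(self, "deltas", d)


@dataclass(frozen=True)
class ImagingParams:
    """Tunable constants of the segmentation pipeline.

    min_area
        Foreground components smaller than this many pixels are removed
        (area opening), default 1000 px.
    erosion_radius
        Radius in px of the disk structuring element used to peel
        residual background from spot rims, default 3.
    max_hole
        Interior background holes smaller than this many pixels are
        filled (area closing), default 1000 px.
    expected_k
        Number of indicator spots the array carries, default 6 (2x3 grid).
    max_registration_shift
        Maximum tolerated pre/post centroid displacement in px before the
        pair is rejected as mis-registered, default 5.
    """

    min_area: int = 1000
    erosion_radius: int = 3
    max_hole: int = 1000
    expected_k: int = 6
    max_registration_shift: float = 5.0


def to_grayscale(image: SensorImage) -> np.ndarray:
    """Luminance raster (BT.601 weights), values in [0, 255]."""
    return np.asarray(image.pixels, dtype=float) @ GRAY_WEIGHTS


def otsu_threshold(gray: np.ndarray) -> tuple[float, np.ndarray]:
    """Binarise a grayscale raster by Otsu's criterion.

    The threshold t maximises the between-class variance of the 256-bin
    histogram over [0, 256); pixels with value <= t form one class, > t
    the other. Ties are broken towards the smallest threshold. The
    returned boolean mask marks the *spot* class, chosen as the class
    whose mean gray level differs more from the mean of the raster's
    border pixels (the border is reliably background on a scanned plate).

    Returns
    -------
    (threshold, mask)

    Raises
    ------
    ValueError
        If the histogram is degenerate (fewer than two occupied bins).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValueError("expected a 2-D grayscale raster")
    hist, _ = np.histogram(gray, bins=256, range=(0, 256))
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: cannot threshold a (near-)constant raster")

    levels = np.arange(256, dtype=float)
    total = hist.sum()
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * levels)
    sum_total = sum0[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (sum_total - sum0) / (total - w0)
        sigma_b = w0 * (total - w0) * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w0 < total), sigma_b, -np.inf)
    t = int(np.argmax(sigma_b))  # argmax takes the first (smallest) maximiser

    low = gray <= t
    border = np.concatenate(
        [gray[0, :], gray[-1, :], gray[1:-1, 0], gray[1:-1, -1]]
    )
    border_mean = border.mean()
    mean_low = gray[low].mean()
    mean_high = gray[~low].mean()
    if abs(mean_high - border_mean) > abs(mean_low - border_mean):
        mask = ~low
    else:
        mask = low
    return float(t), mask


def area_open(mask: np.ndarray, min_area: int = 1000) -> np.ndarray:
    """Remove 8-connected foreground components smaller than ``min_area`` px.

    Components with pixel count >= min_area are preserved bit-exactly
    (strict "smaller than" removal).
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    # max_size removes components of size <= value, so strict "< min_area"
    # removal is max_size = min_area - 1.
    return morphology.remove_small_objects(mask, max_size=min_area - 1, connectivity=2)


def _fill_small_holes(mask: np.ndarray, max_hole: int) -> np.ndarray:
    """Fill 8-connected background components not touching the border and
    smaller than ``max_hole`` px."""
    bg = ~mask
    lab = measure.label(bg, connectivity=2)
    if lab.max() == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    border_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[1:-1, 0], lab[1:-1, -1]])
    )
    fill = np.zeros(sizes.shape, dtype=bool)
    fill[1:] = sizes[1:] < max_hole
    fill[border_labels] = False
    out = mask.copy()
    out[fill[lab]] = True
    return out


def refine_mask(mask: np.ndarray, erosion_radius: int = 3, max_hole: int = 1000) -> np.ndarray:
    """Erode with a disk element, then fill small interior holes.

    Erosion peels residual background clinging to spot rims; hole
    filling (area closing) recovers interior pixels lost to suboptimal
    thresholding. Holes are background components of size < ``max_hole``
    that do not touch the raster border.
    """
    if erosion_radius < 1:
        raise ValueError("erosion_radius must be >= 1")
    if max_hole < 1:
        raise ValueError("max_hole must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    # border_value=0: pixels outside the raster count as background, so
    # foreground touching the border erodes like any other boundary.
    eroded = ndimage.binary_erosion(
        mask, structure=morphology.disk(erosion_radius), border_value=0
    )
    return _fill_small_holes(eroded, max_hole)


def label_spots(mask: np.ndarray, expected_k: int = 6) -> SpotLabelMap:
    """Label 8-connected components 1..K in reading order.

    Components are grouped into rows by clustering centroid rows (a gap
    larger than half the median component height starts a new row); rows
    run top to bottom and labels increase left to right within a row.

    Raises
    ------
    SegmentationError
        If the component count differs from ``expected_k``.
    """
    if expected_k < 1:
        raise ValueError("expected_k must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    if len(props) != expected_k:
        raise SegmentationError(
            f"segmentation found {len(props)} components, expected {expected_k}"
        )

    heights = [p.bbox[2] - p.bbox[0] for p in props]
    gap = float(np.median(heights)) / 2.0
    order = sorted(props, key=lambda p: p.centroid[0])
    rows: list[list] = [[order[0]]]
    for p in order[1:]:
        if p.centroid[0] - rows[-1][-1].centroid[0] > gap:
            rows.append([p])
        else:
            rows[-1].append(p)

    relabel = np.zeros(lab.max() + 1, dtype=np.int32)
    centroids = []
    k = 0
    for row in rows:
        for p in sorted(row, key=lambda p: p.centroid[1]):
            k += 1
            relabel[p.label] = k
            centroids.append((float(p.centroid[0]), float(p.centroid[1])))
    return SpotLabelMap(labels=relabel[lab], centroids=tuple(centroids))


def apply_mask(image: SensorImage, labels: SpotLabelMap) -> SensorImage:
    """Zero out background pixels (label 0), leaving spot pixels unchanged."""
    if image.pixels.shape[:2] != labels.labels.shape:
        raise ValueError("image and label map shapes differ")
    out = image.pixels.copy()
    out[labels.labels == 0] = 0
    return SensorImage(pixels=out, phase=image.phase, time_min=image.time_min)


def difference_map(
    pre: SensorImage,
    post: SensorImage,
    labels: SpotLabelMap,
    post_labels: Optional[SpotLabelMap] = None,
    max_registration_shift: float = 5.0,
) -> DifferenceMap:
    """Absolute per-pixel colour change |post - pre| inside labelled spots.

    ``labels`` must come from the pre-exposure image; correspondence
    between captures is by label index (the array is assumed untouched
    between captures). If ``post_labels`` is supplied, paired centroids
    must agree within ``max_registration_shift`` px, else the pair is
    rejected as mis-registered.
    """
    if pre.pixels.shape != post.pixels.shape:
        raise ValueError("pre and post images must have identical shapes")
    if pre.phase != Phase.PRE or post.phase != Phase.POST:
        raise ValueError("phase fields inconsistent: expected (pre, post)")
    if post_labels is not None:
        if post_labels.n_spots != labels.n_spots:
            raise SegmentationError(
                f"pre/post spot counts differ: {labels.n_spots} vs {post_labels.n_spots}"
            )
        for k, (a, b) in enumerate(zip(labels.centroids, post_labels.centroids), start=1):
            d = float(np.hypot(a[0] - b[0], a[1] - b[1]))
            if d > max_registration_shift:
                raise SegmentationError(
                    f"spot {k} moved {d:.1f} px between captures "
                    f"(max {max_registration_shift}); images mis-registered"
                )
    deltas = np.abs(post.pixels.astype(float) - pre.pixels.astype(float))
    deltas[labels.labels == 0] = 0.0
    return DifferenceMap(deltas=deltas, labels=labels)


def rescale_for_display(
    dm: DifferenceMap, low: float = DISPLAY_RANGE[0], high: float = DISPLAY_RANGE[1]
) -> np.ndarray:
    """Map a difference map onto the full 8-bit range for visualisation.

    Each channel value v is clipped to [low, high] (default the 6-bit
    window 3..62) and linearly rescaled to [0, 255]; rounding is
    half-away-from-zero. Returns a uint8 (H, W, 3) raster.
    """
    if high <= low:
        raise ValueError("high must exceed low")
    v = np.clip(dm.deltas, low, high)
    scaled = (v - low) * 255.0 / (high - low)
    return np.floor(scaled + 0.5).astype(np.uint8)


def segment_array(image: SensorImage, params: ImagingParams = ImagingParams()) -> SpotLabelMap:
    """Full segmentation pipeline: grayscale -> Otsu -> area opening ->
    erosion + hole filling -> reading-order labels."""
    gray = to_grayscale(image)
    _, mask = otsu_threshold(gray)
    mask = area_open(mask, params.min_area)
    mask = refine_mask(mask, params.erosion_radius, params.max_hole)
    return label_spots(mask, params.expected_k)
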