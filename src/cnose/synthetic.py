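"""Synthetic colorimetric sensor-array generator with ground truth.

Emulates a 2x3 grid of circular indicator spots on a light silica-plate
background, photographed before and after exposure to the headspace of
an oil sample. Post-exposure spot colours shift by a class-dependent
amount: a linear mixing model interpolates each dye's colour shift
between the pure quince seed oil response and the pure adulterant
(sunflower or sesame) response according to the adulteration fraction.
Pixel noise, a linear illumination gradient and first-order saturation
kinetics provide the nuisance structure; every sample carries its
ground-truth masks, true shift matrix and class label, so the whole
imaging + feature + classification pipeline is testable without
laboratory data.

Default geometry: 480 x 640 px image, spot radius 40 px (area ~5027 px,
comfortably above the 1000 px area-opening threshold), 2x3 grid with
160 px centre spacing — a 2 cm plate with 5 mm spot pitch imaged at
roughly 80 px/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import CSAError, SegmentationError
from .features import FEATURE_COLUMNS, extract_features
from .imaging import ImagingParams, Phase, SensorImage, SpotLabelMap
from .scheme import CLASS_DEFINITIONS, class_label

__all__ = ["SyntheticSpec", "GroundTruth", "class_shift", "render_pair",
           "render_timelapse", "make_dataset"]


def _default_base_colors() -> np.ndarray:
    # Pre-exposure dye colours (S1..S6), mid-range so shifts never clip.
    return np.array(
        [
            [140, 90, 160],   # S1 methyl violet
            [180, 120, 90],   # S2 chlorophenol red
            [80, 110, 170],   # S3 Nile blue
            [190, 120, 70],   # S4 methyl orange
            [170, 90, 100],   # S5 alizarin
            [170, 120, 110],  # S6 cresol red
        ],
        dtype=float,
    )


def _default_shift_q() -> np.ndarray:
    return np.array(
        [[-40, 10, 30], [20, -30, 10], [15, 25, -35],
         [-25, 20, -10], [30, -15, 20], [-20, -25, 15]],
        dtype=float,
    )


def _default_shift_su() -> np.ndarray:
    # Sign-consistent with the quince response per channel, so blended
    # fingerprints interpolate without sign crossings and the distance
    # from the pure-quince fingerprint grows monotonically with fraction.
    return np.array(
        [[-10, 45, 5], [40, -5, 40], [40, 2, -8],
         [-60, 45, -35], [5, -45, 55], [-45, -5, 50]],
        dtype=float,
    )


def _default_shift_se() -> np.ndarray:
    # Dyes S1, S4, S6 respond most strongly to sesame.
    return np.array(
        [[-85, 55, 70], [8, -45, 3], [45, 40, -5],
         [-70, 65, -45], [12, -5, 50], [-65, -70, 60]],
        dtype=float,
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative description of a simulated sensor array.

    noise_sd is the per-pixel, per-channel Gaussian SD in gray levels;
    illumination_gradient the maximum fractional brightness slope of a
    random linear shading field (shared between the pre and post capture
    of a sample); kinetics_tau_min the first-order saturation time
    constant in minutes (tau = 15 puts the response within 2% of its
    plateau near 60 min).
    """

    image_size: tuple = (480, 640)
    grid_shape: tuple = (2, 3)
    spacing: float = 160.0
    spot_radius: float = 40.0
    background_color: tuple = (200, 200, 200)
    base_colors: np.ndarray = field(default_factory=_default_base_colors)
    shift_pure_q: np.ndarray = field(default_factory=_default_shift_q)
    shift_pure_su: np.ndarray = field(default_factory=_default_shift_su)
    shift_pure_se: np.ndarray = field(default_factory=_default_shift_se)
    noise_sd: float = 3.0
    illumination_gradient: float = 0.05
    kinetics_tau_min: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_colors", "shift_pure_q", "shift_pure_su", "shift_pure_se"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (6, 3):
                raise ValueError(f"{name} must be a 6x3 matrix, got {arr.shape}")
            object.__setattr__(self, name, arr)
        if np.pi * self.spot_radius**2 <= 1000:
            raise ValueError(
                "spot_radius too small: spot area must exceed the 1000 px "
                "area-opening threshold"
            )
        for name in ("shift_pure_q", "shift_pure_su", "shift_pure_se"):
            if np.abs(getattr(self, name)).max() > 255:
                raise ValueError(f"{name} entries must lie in [-255, 255]")
        if self.noise_sd < 0 or self.illumination_gradient < 0:
            raise ValueError("noise_sd and illumination_gradient must be nonnegative")
        h, w = self.image_size
        centers = self.spot_centers()
        r = self.spot_radius
        for cr, cc in centers:
            if cr - r < 0 or cr + r >= h or cc - r < 0 or cc + r >= w:
                raise ValueError("spots exceed image bounds")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
                if d < 2 * r:
                    raise ValueError("spots overlap")

    def spot_centers(self) -> list[tuple[float, float]]:
        """Grid centres in reading order (row-major), centred on the image."""
        h, w = self.image_size
        rows, cols = self.grid_shape
        r0 = (h - (rows - 1) * self.spacing) / 2.0
        c0 = (w - (cols - 1) * self.spacing) / 2.0
        return [
            (r0 + i * self.spacing, c0 + j * self.spacing)
            for i in range(rows)
            for j in range(cols)
        ]


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows about a sample: true masks, true colour
    shift, class label and mixture composition."""

    masks: SpotLabelMap
    true_shift: np.ndarray
    class_label: str
    mixture_fraction: float
    adulterant: str


def class_shift(spec: SyntheticSpec, adulterant: str, fraction: float) -> np.ndarray:
    """True 6x3 post-pre colour shift for a blend: linear interpolation
    between the pure quince response and the pure adulterant response."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    if adulterant == "none" or fraction == 0.0:
        return spec.shift_pure_q.copy()
    if adulterant == "sunflower":
        pure = spec.shift_pure_su
    elif adulterant == "sesame":
        pure = spec.shift_pure_se
    else:
        raise ValueError(f"unknown adulterant {adulterant!r}")
    return (1.0 - fraction) * spec.shift_pure_q + fraction * pure


def _coverage(spec: SyntheticSpec) -> np.ndarray:
    """Antialiased disk coverage per spot, shape (6, H, W)."""
    h, w = spec.image_size
    rr, cc = np.mgrid[0:h, 0:w]
    cov = np.empty((len(spec.spot_centers()), h, w), dtype=float)
    for k, (cr, ccen) in enumerate(spec.spot_centers()):
        dist = np.hypot(rr - cr, cc - ccen)
        cov[k] = np.clip(spec.spot_radius + 0.5 - dist, 0.0, 1.0)
    return cov


def _illumination(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Random linear shading field, fractional slope up to the spec max."""
    h, w = spec.image_size
    theta = rng.uniform(0, 2 * np.pi)
    m = rng.uniform(0, spec.illumination_gradient)
    rr, cc = np.mgrid[0:h, 0:w]
    ramp = np.cos(theta) * (cc - w / 2) / w + np.sin(theta) * (rr - h / 2) / h
    return 1.0 + m * ramp


def _compose(
    spec: SyntheticSpec,
    coverage: np.ndarray,
    shift: Optional[np.ndarray],
    illum: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    img = np.ones(spec.image_size + (3,), dtype=float) * np.asarray(
        spec.background_color, dtype=float
    )
    colors = spec.base_colors if shift is None else spec.base_colors + shift
    for k in range(coverage.shape[0]):
        cov = coverage[k][..., None]
        img = img * (1.0 - cov) + colors[k] * cov
    img *= illum[..., None]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _truth_labels(spec: SyntheticSpec, coverage: np.ndarray) -> SpotLabelMap:
    # only fully covered pixels belong to the true mask, so masked means
    # of the rendered shift are free of antialiased-rim dilution
    labels = np.zeros(spec.image_size, dtype=np.int32)
    for k in range(coverage.shape[0]):
        labels[coverage[k] >= 1.0] = k + 1
    return SpotLabelMap(labels=labels, centroids=tuple(spec.spot_centers()))


def render_pair(
    spec: SyntheticSpec,
    adulterant: str,
    fraction: float,
    sample_seed: Optional[int] = None,
) -> tuple[SensorImage, SensorImage, GroundTruth]:
    """Render one pre/post capture pair plus its ground truth.

    All randomness (illumination field, pre noise, post noise, in that
    order) comes from ``sample_seed`` (default: the spec seed), so the
    same seed reproduces bit-identical images.
    """
    seed = spec.seed if sample_seed is None else sample_seed
    rng = np.random.default_rng(seed)
    shift = class_shift(spec, adulterant, fraction)
    cov = _coverage(spec)
    illum = _illumination(spec, rng)
    pre = _compose(spec, cov, None, illum, rng)
    post = _compose(spec, cov, shift, illum, rng)
    truth = GroundTruth(
        masks=_truth_labels(spec, cov),
        true_shift=shift,
        class_label=class_label(adulterant, fraction),
        mixture_fraction=fraction,
        adulterant=adulterant,
    )
    return (
        SensorImage(pre, phase=Phase.PRE, time_min=0.0),
        SensorImage(post, phase=Phase.POST),
        truth,
    )


def render_timelapse(
    spec: SyntheticSpec,
    adulterant: str,
    fraction: float,
    times_min: Sequence[float],
    sample_seed: Optional[int] = None,
) -> tuple[SensorImage, list[SensorImage]]:
    """Render a pre capture and exposure frames at the given times.

    The colour shift at time t is scaled by 1 - exp(-t / tau); frame
    noise is independent per frame, the illumination field is shared.
    """
    times = np.asarray(times_min, dtype=float)
    if times.size == 0:
        raise ValueError("times_min must be nonempty")
    if (np.diff(times) <= 0).any():
        raise ValueError("times_min must be strictly increasing")
    seed = spec.seed if sample_seed is None else sample_seed
    rng = np.random.default_rng(seed)
    shift = class_shift(spec, adulterant, fraction)
    cov = _coverage(spec)
    illum = _illumination(spec, rng)
    pre = _compose(spec, cov, None, illum, rng)
    frames = []
    for t in times:
        scale = 1.0 - np.exp(-t / spec.kinetics_tau_min)
        px = _compose(spec, cov, shift * scale, illum, rng)
        frames.append(SensorImage(px, phase=Phase.POST, time_min=float(t)))
    return SensorImage(pre, phase=Phase.PRE, time_min=0.0), frames


def make_dataset(
    spec: SyntheticSpec,
    n_per_class: int = 8,
    sample_seed: Optional[int] = None,
    params: ImagingParams = ImagingParams(),
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Render and analyse a labelled dataset across all 13 classes.

    For each class, ``n_per_class`` pre/post pairs are rendered and
    pushed through the full segmentation + feature pipeline; the default
    8 per class yields the study size of 104 samples. Returns the
    feature table (sample_id, label, s1_r..s6_b) and per-sample ground
    truth.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seed = spec.seed if sample_seed is None else sample_seed
    n_total = len(CLASS_DEFINITIONS) * n_per_class
    child_seeds = (
        np.random.SeedSequence(seed).generate_state(n_total) & 0x7FFFFFFF
    )
    rows = []
    truths = []
    i = 0
    for label, adulterant, fraction in CLASS_DEFINITIONS:
        for rep in range(n_per_class):
            s = int(child_seeds[i])
            i += 1
            pre, post, truth = render_pair(spec, adulterant, fraction, sample_seed=s)
            try:
                vec, _ = extract_features(pre, post, params)
            except SegmentationError as exc:
                raise CSAError(
                    f"segmentation failed for sample {label}_{rep:02d} "
                    f"(sample_seed={s}): {exc}"
                ) from exc
            rows.append([f"{label}_{rep:02d}", label, *vec.tolist()])
            truths.append(truth)
    df = pd.DataFrame(rows, columns=["sample_id", "label", *FEATURE_COLUMNS])
    return df, truths
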