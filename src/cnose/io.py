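"""File formats: PNG/TIFF images, CSV tables, JSON configuration.

All artefacts are plain text or standard raster formats; model objects
serialise to JSON (see `cnose.model`), never opaque binaries.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import asdict, dataclass, fields
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .chemometrics import ConfusionMatrix
from .exceptions import DataFormatError
from .features import FEATURE_COLUMNS, ResponseProfile
from .imaging import Phase, SensorImage, SpotLabelMap
from .scheme import CLASS_ORDER

__all__ = [
    "read_image",
    "write_image",
    "write_label_map",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
    "write_profile",
    "read_profile",
    "write_confusion_csv",
    "read_confusion_csv",
    "parse_confusion_table",
    "RunConfig",
    "load_run_config",
]


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def read_image(path, phase: Phase = Phase.PRE, time_min: Optional[float] = None) -> SensorImage:
    """Read an 8-bit RGB PNG/TIFF. An alpha channel is stripped with a warning."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn(f"{path}: alpha channel stripped", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise DataFormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise DataFormatError(f"{path}: expected 8-bit channels, got {arr.dtype}")
    return SensorImage(pixels=arr, phase=phase, time_min=time_min)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a uint8 raster (RGB or single-channel) as PNG/TIFF."""
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))


def write_label_map(path, labels: SpotLabelMap) -> None:
    """Write a label raster as 16-bit single-channel PNG."""
    iio.imwrite(path, labels.labels.astype(np.uint16))


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as 8-bit PNG (0/255)."""
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Feature tables and profiles
# ---------------------------------------------------------------------------

def write_feature_table(df: pd.DataFrame, path) -> None:
    cols = ["sample_id", "label", *FEATURE_COLUMNS]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataFormatError(f"feature table is missing columns: {missing}")
    df[cols].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "label", *FEATURE_COLUMNS) if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: feature table is missing columns: {missing}")
    return df


def write_profile(profile: ResponseProfile, path) -> None:
    pd.DataFrame({"time_min": profile.times_min, "norm": profile.norms}).to_csv(
        path, index=False
    )


def read_profile(path) -> ResponseProfile:
    df = pd.read_csv(path)
    if not {"time_min", "norm"}.issubset(df.columns):
        raise DataFormatError(f"{path}: expected columns time_min, norm")
    return ResponseProfile(
        times_min=df["time_min"].to_numpy(float), norms=df["norm"].to_numpy(float)
    )


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------

def write_confusion_csv(cm: ConfusionMatrix, path) -> None:
    pd.DataFrame(cm.counts, index=cm.class_order, columns=cm.class_order).to_csv(path)


def read_confusion_csv(path) -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(class_order=tuple(df.index), counts=df.to_numpy(int))


def parse_confusion_table(text: str) -> ConfusionMatrix:
    """Parse a whitespace/comma-delimited square confusion table with row
    labels into the canonical 13-class order.

    Columns are mapped positionally onto the row-label order, which
    tolerates header typos in printed tables; rows must all carry the
    same number of counts (ragged tables are rejected).
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise DataFormatError("confusion table needs a header and at least one row")
    rows = []
    labels = []
    for ln in lines[1:]:
        parts = re.split(r"[,\s]+", ln)
        labels.append(parts[0])
        try:
            rows.append([int(p) for p in parts[1:]])
        except ValueError as exc:
            raise DataFormatError(f"non-integer count in row {parts[0]!r}") from exc
    k = len(labels)
    if any(len(r) != k for r in rows):
        raise DataFormatError("ragged confusion table: rows and columns disagree")
    order = tuple(labels)
    if set(order) == set(CLASS_ORDER):
        # Reorder rows (and columns positionally) into the canonical scheme.
        perm = [labels.index(c) for c in CLASS_ORDER]
        counts = np.asarray(rows, int)[np.ix_(perm, perm)]
        order = tuple(CLASS_ORDER)
    else:
        counts = np.asarray(rows, int)
    return ConfusionMatrix(class_order=order, counts=counts)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """JSON-backed run configuration with the pipeline's fixed constants.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """

    schema_version: int = 1
    min_area: int = 1000
    erosion_radius: int = 3
    max_hole: int = 1000
    expected_k: int = 6
    display_low: float = 3.0
    display_high: float = 62.0
    n_iter: int = 100
    folds: int = 10
    n_repeats: int = 10
    train_frac: float = 0.7
    variance_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_area < 1 or self.erosion_radius < 1 or self.max_hole < 1:
            raise ValueError("morphology parameters must be >= 1")
        if self.expected_k < 1:
            raise ValueError("expected_k must be >= 1")
        if self.display_high <= self.display_low:
            raise ValueError("display_high must exceed display_low")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.n_iter < 1 or self.folds < 2 or self.n_repeats < 1:
            raise ValueError("n_iter, folds, n_repeats out of range")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = json.load(fh)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise DataFormatError(f"unknown configuration keys: {sorted(unknown)}")
    return RunConfig(**data)
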