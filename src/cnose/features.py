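"""Fingerprint feature extraction and exposure-time analysis.

A six-spot array yields an 18-element feature vector: the mean absolute
colour change per spot and per RGB channel, in 8-bit gray levels. The
Euclidean norm of that vector over time gives the response profile used
to pick the exposure time at which the colour change saturates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import CSAError
from .imaging import (
    DifferenceMap,
    ImagingParams,
    Phase,
    SensorImage,
    SpotLabelMap,
    difference_map,
    segment_array,
)

__all__ = [
    "FEATURE_COLUMNS",
    "ResponseProfile",
    "spot_mean_rgb",
    "assemble_feature_vector",
    "euclidean_norm",
    "response_profile",
    "steady_state_time",
    "optimal_exposure",
    "fit_saturation",
    "extract_features",
    "exposure_profile",
]

#: CSV column names of the 18-element fingerprint, spot-major, RGB within spot.
FEATURE_COLUMNS = [f"s{k}_{c}" for k in range(1, 7) for c in "rgb"]


def spot_mean_rgb(dm: DifferenceMap) -> np.ndarray:
    """Per-spot, per-channel mean of the difference map, shape (K, 3)."""
    lab = dm.labels.labels
    k = dm.labels.n_spots
    out = np.empty((k, 3), dtype=float)
    for i in range(1, k + 1):
        sel = lab == i
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"spot {i} has zero pixels")
        out[i - 1] = dm.deltas[sel].mean(axis=0)
    return out


def assemble_feature_vector(means: np.ndarray) -> np.ndarray:
    """Flatten a 6x3 table of channel means row-major into the 18-vector
    (spot 1 R, spot 1 G, spot 1 B, ..., spot 6 B)."""
    means = np.asarray(means, dtype=float)
    if means.shape != (6, 3):
        raise ValueError(f"expected a 6x3 table of channel means, got {means.shape}")
    return means.reshape(18).copy()


def euclidean_norm(v: np.ndarray) -> float:
    """L2 norm of a feature vector — the scalar response magnitude."""
    return float(np.linalg.norm(np.asarray(v, dtype=float)))


@dataclass(frozen=True)
class ResponseProfile:
    """Response magnitude over exposure time: strictly increasing sample
    times (minutes) and the fingerprint norm at each."""

    times_min: np.ndarray
    norms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        n = np.asarray(self.norms, dtype=float)
        if t.shape != n.shape or t.ndim != 1:
            raise ValueError("times and norms must be 1-D and the same length")
        if len(t) and (np.diff(t) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (t < 0).any() or (n < 0).any():
            raise ValueError("times and norms must be nonnegative")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "norms", n)


def response_profile(frames: Sequence[tuple[float, np.ndarray]]) -> ResponseProfile:
    """Build a profile from (time_min, feature_vector) pairs in time order."""
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    times = np.array([t for t, _ in frames], dtype=float)
    norms = np.array([euclidean_norm(v) for _, v in frames])
    return ResponseProfile(times_min=times, norms=norms)


def steady_state_time(
    profile: ResponseProfile, epsilon: float = 0.02, window_min: float = 10.0
) -> Optional[float]:
    """Earliest sampled time after which the response stays flat.

    Returns the first sampled time t such that every later sample within
    (t, t + window_min] differs from norm(t) by at most epsilon * max(norms).
    Times whose window extends past the profile cannot be certified and
    are not considered. Returns None if no time qualifies.
    """
    if epsilon <= 0 or window_min <= 0:
        raise ValueError("epsilon and window_min must be positive")
    t, n = profile.times_min, profile.norms
    peak = n.max() if len(n) else 0.0
    if peak == 0:
        raise CSAError("no response: profile is identically zero")
    tol = epsilon * peak
    for i in range(len(t)):
        if t[i] + window_min > t[-1]:
            break
        sel = (t > t[i]) & (t <= t[i] + window_min)
        if np.all(np.abs(n[sel] - n[i]) <= tol):
            return float(t[i])
    return None


def optimal_exposure(
    profiles: Sequence[tuple[str, ResponseProfile]],
    epsilon: float = 0.02,
    window_min: float = 10.0,
) -> str:
    """Pick the candidate condition with the largest final-time response norm.

    Ties are broken by earliest steady-state onset, then by input order.
    """
    if len(profiles) == 0:
        raise ValueError("no candidate profiles")
    best = None
    for order, (name, prof) in enumerate(profiles):
        if len(prof.norms) == 0:
            raise ValueError(f"profile {name!r} is empty")
        final = prof.norms[-1]
        try:
            ss = steady_state_time(prof, epsilon=epsilon, window_min=window_min)
        except CSAError:
            ss = None
        ss_key = ss if ss is not None else np.inf
        key = (-final, ss_key, order)
        if best is None or key < best[0]:
            best = (key, name)
    return best[1]


def fit_saturation(profile: ResponseProfile) -> tuple[float, float]:
    """Fit A * (1 - exp(-t / tau)) to a response profile.

    Returns (amplitude, tau_min). Used to recover the first-order
    kinetics time constant from a time-lapse.
    """
    t, n = profile.times_min, profile.norms

    def model(t, a, tau):
        return a * (1.0 - np.exp(-t / tau))

    a0 = float(n.max())
    tau0 = max(float(t[-1]) / 4.0, 1e-3)
    popt, _ = curve_fit(model, t, n, p0=[a0, tau0], maxfev=10000)
    return float(popt[0]), float(popt[1])


def extract_features(
    pre: SensorImage,
    post: SensorImage,
    params: ImagingParams = ImagingParams(),
    check_registration: bool = True,
) -> tuple[np.ndarray, SpotLabelMap]:
    """Run the full pipeline on one pre/post pair.

    Segments the pre image, optionally segments the post image to verify
    registration, and returns (18-element feature vector, label map).
    """
    labels = segment_array(pre, params)
    post_labels = segment_array(post, params) if check_registration else None
    dm = difference_map(
        pre, post, labels, post_labels=post_labels,
        max_registration_shift=params.max_registration_shift,
    )
    return assemble_feature_vector(spot_mean_rgb(dm)), labels


def exposure_profile(
    pre: SensorImage,
    frames: Sequence[SensorImage],
    params: ImagingParams = ImagingParams(),
) -> ResponseProfile:
    """Response profile of a time-lapse: segment once on the pre capture,
    then difference every frame against it."""
    labels = segment_array(pre, params)
    pairs = []
    for frame in frames:
        if frame.time_min is None:
            raise ValueError("every frame needs a time_min stamp")
        post = SensorImage(frame.pixels, phase=Phase.POST, time_min=frame.time_min)
        dm = difference_map(pre, post, labels)
        pairs.append((frame.time_min, assemble_feature_vector(spot_mean_rgb(dm))))
    pairs.sort(key=lambda p: p[0])
    return response_profile(pairs)
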