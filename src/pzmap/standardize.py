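"""Landmark-based intensity standardization and z-score normalization.

MR intensities carry no fixed tissue meaning: the same tissue class can map
to different gray values between slices and acquisitions ("non-standardness").
The standardization used here follows the Nyul-style landmark scheme: for each
slice the median and a low/high percentile pair are located, a standard scale
``[s1, s2]`` is fixed, and each slice is warped onto it by a piecewise-linear
map with three landmarks so that every slice's median lands on the same
standard-scale value ``mu_s`` (the mean of the training slices' mapped
medians).  A final z-score pass brings each modality to zero mean / unit
standard deviation over the analysis region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SliceLandmarks",
    "StandardScale",
    "compute_landmarks",
    "train_standard_scale",
    "standardize_slice",
    "standardize_stack",
    "zscore_normalize",
]

#: default high landmark percentile (the low landmark is the 0th percentile,
#: i.e. the minimum)
HIGH_PERCENTILE = 99.8

#: default standard-scale endpoints (12-bit-like range, following the
#: landmark-standardization literature's convention)
DEFAULT_S1 = 1.0
DEFAULT_S2 = 4095.0


@dataclass(frozen=True)
class SliceLandmarks:
    """Median and percentile landmarks of one slice.

    ``p_low`` is the 0th-percentile (minimum) intensity and ``p_high`` the
    99.8th-percentile intensity, computed with linear interpolation between
    order statistics.
    """

    m: float
    p_low: float
    p_high: float

    def __post_init__(self) -> None:
        if not (self.p_low <= self.m <= self.p_high):
            raise ValueError(
                f"landmarks must satisfy p_low <= m <= p_high, got "
                f"({self.p_low}, {self.m}, {self.p_high})"
            )


@dataclass(frozen=True)
class StandardScale:
    """Trained landmark mapping for one modality.

    ``mu_s`` is the arithmetic mean of the training slices' medians after each
    has been mapped onto the standard scale ``[s1, s2]``.
    """

    s1: float
    s2: float
    mu_s: float
    p_percentiles: tuple[float, float] = (0.0, HIGH_PERCENTILE)
    n_slices_trained: int = 1

    def __post_init__(self) -> None:
        if not (self.s1 < self.mu_s < self.s2):
            raise ValueError(
                f"standard scale requires s1 < mu_s < s2, got "
                f"({self.s1}, {self.mu_s}, {self.s2})"
            )
        if self.n_slices_trained < 1:
            raise ValueError("StandardScale must be trained from >= 1 slice")


def _masked_values(image: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty slice")
    if mask is None:
        return image.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != slice shape {image.shape}")
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("mask selects no pixels")
    return vals


def compute_landmarks(
    slice_: np.ndarray, mask: np.ndarray | None = None
) -> SliceLandmarks:
    """Median and 0th/99.8th-percentile intensities of a (masked) slice.

    Percentiles use linear interpolation between order statistics; the 0th
    percentile is the minimum.  A constant slice is allowed and yields
    ``p_low == m == p_high``.
    """
    vals = _masked_values(slice_, mask)
    m = float(np.median(vals))
    p_low = float(np.min(vals))
    p_high = float(np.percentile(vals, HIGH_PERCENTILE, method="linear"))
    return SliceLandmarks(m=m, p_low=p_low, p_high=p_high)


def _map_to_scale(value: float, lm: SliceLandmarks, s1: float, s2: float) -> float:
    """Two-point linear map sending [p_low, p_high] -> [s1, s2]."""
    return s1 + (value - lm.p_low) * (s2 - s1) / (lm.p_high - lm.p_low)


def train_standard_scale(
    slices: list[np.ndarray],
    s1: float = DEFAULT_S1,
    s2: float = DEFAULT_S2,
    masks: list[np.ndarray] | None = None,
) -> StandardScale:
    """Train the standard scale for one modality.

    For each slice the median is mapped onto ``[s1, s2]`` by the linear map
    anchored at its own percentile landmarks; ``mu_s`` is the mean of these
    mapped medians.  Run once per modality.  Slices with a degenerate
    intensity range (``p_low == p_high``) are skipped with a warning.
    """
    if len(slices) == 0:
        raise ValueError("need at least one slice to train a StandardScale")
    if s2 <= s1:
        raise ValueError("require s1 < s2")
    mapped = []
    for i, sl in enumerate(slices):
        mask = None if masks is None else masks[i]
        lm = compute_landmarks(sl, mask)
        if lm.p_high == lm.p_low:
            warnings.warn(f"slice {i} has a degenerate intensity range; skipped")
            continue
        mapped.append(_map_to_scale(lm.m, lm, s1, s2))
    if not mapped:
        raise ValueError("all slices degenerate; cannot train StandardScale")
    mu_s = float(np.mean(mapped))
    return StandardScale(
        s1=float(s1),
        s2=float(s2),
        mu_s=mu_s,
        p_percentiles=(0.0, HIGH_PERCENTILE),
        n_slices_trained=len(mapped),
    )


def standardize_slice(
    slice_: np.ndarray,
    scale: StandardScale,
    mask: np.ndarray | None = None,
    clamp: bool = False,
) -> np.ndarray:
    """Map one slice onto the standard scale.

    Piecewise-linear with three landmarks: ``[p_low, m] -> [s1, mu_s]`` and
    ``[m, p_high] -> [mu_s, s2]``.  Values outside ``[p_low, p_high]`` are
    linearly extrapolated on their segment (or clamped with ``clamp=True``).
    Landmarks are computed inside ``mask`` when given, but the map is applied
    to every pixel of the slice.
    """
    img = np.asarray(slice_, dtype=float)
    lm = compute_landmarks(img, mask)
    out = np.empty_like(img)

    lower = img <= lm.m
    if lm.m > lm.p_low:
        a = (scale.mu_s - scale.s1) / (lm.m - lm.p_low)
        out[lower] = scale.s1 + (img[lower] - lm.p_low) * a
    else:
        warnings.warn("degenerate lower segment (m == p_low); collapsed to mu_s")
        out[lower] = scale.mu_s
    upper = ~lower
    if lm.p_high > lm.m:
        a = (scale.s2 - scale.mu_s) / (lm.p_high - lm.m)
        out[upper] = scale.mu_s + (img[upper] - lm.m) * a
    else:
        warnings.warn("degenerate upper segment (m == p_high); collapsed to mu_s")
        out[upper] = scale.mu_s
    if clamp:
        np.clip(out, scale.s1, scale.s2, out=out)
    return out


def standardize_stack(
    stack: np.ndarray,
    scale: StandardScale,
    mask: np.ndarray | None = None,
    clamp: bool = False,
) -> np.ndarray:
    """Apply :func:`standardize_slice` to every slice of a (n, H, W) stack."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3-D (slices, rows, cols)")
    out = np.empty_like(stack)
    for i in range(stack.shape[0]):
        m = None if mask is None else np.asarray(mask)[i]
        out[i] = standardize_slice(stack[i], scale, mask=m, clamp=clamp)
    return out


def zscore_normalize(
    stack: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Z-score a modality stack to mean 0 / standard deviation 1.

    The mean and standard deviation (population convention, divide by n) are
    computed over the masked region of the whole stack; the affine transform
    is applied everywhere.  A constant input has zero variance and is an
    error.
    """
    stack = np.asarray(stack, dtype=float)
    if mask is None:
        vals = stack.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != stack.shape:
            raise ValueError("mask shape must match stack shape")
        vals = stack[mask]
        if vals.size == 0:
            raise ValueError("mask selects no pixels")
    mu = float(np.mean(vals))
    sd = float(np.std(vals))  # population (ddof=0)
    if sd == 0.0:
        raise ValueError("constant input: zero variance, cannot z-score")
    return (stack - mu) / sd
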