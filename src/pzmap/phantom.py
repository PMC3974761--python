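"""Synthetic multimodal phantoms and Gaussian training sets.

No clinical data ships with the package, so every downstream stage is
exercised on synthetic inputs that carry the statistical structure the
pipeline assumes:

* textured background vs. lesion regions that differ in mean, variance and
  spatial autocorrelation (lesions are smoothed with a different kernel width
  so second-order and phase features carry signal beyond the mean shift);
* a smooth multiplicative bias field per slice;
* per-slice linear gain/offset distortions (intensity non-standardness);
* heavy class imbalance (lesion pixels are a small fraction of the region of
  interest) and an optional fraction of flipped labels.

The region of interest is a half-annulus band in the lower image half,
standing in for the peripheral zone of the prostate, where most tumors arise
and where the classification is restricted.  Lesions are random ellipses
deformed by smoothed noise — cancerous structures have no canonical shape,
and circular boundaries would be trivially separable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "GaussianSetSpec",
    "Phantom",
    "generate_phantom",
    "generate_gaussian_set",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic multimodal phantom.

    Intensities are in arbitrary units; distances in pixels.  The smoothing
    sigmas set the spatial autocorrelation length (texture scale) of each
    tissue class.  ``bias_amplitude`` is the peak fractional deviation of the
    multiplicative bias field; ``slice_gain_sigma`` / ``slice_offset_sigma``
    scale the per-slice linear intensity distortions.
    """

    n_slices: int = 4
    height: int = 64
    width: int = 64
    n_lesions_per_slice: int = 2
    lesion_radius_range: tuple[float, float] = (4.0, 7.0)
    background_mean: float = 100.0
    lesion_mean: float = 130.0
    background_sigma: float = 20.0
    lesion_sigma: float = 20.0
    background_smoothing_sigma: float = 0.6
    lesion_smoothing_sigma: float = 1.8
    bias_amplitude: float = 0.1
    slice_gain_sigma: float = 0.05
    slice_offset_sigma: float = 5.0
    label_noise_fraction: float = 0.0
    min_lesion_area: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.height < 8 or self.width < 8:
            raise ValueError("non-positive or too-small phantom dimensions")
        if self.n_lesions_per_slice < 0:
            raise ValueError("n_lesions_per_slice must be >= 0")
        lo, hi = self.lesion_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid lesion_radius_range")
        if 2 * hi >= min(self.height, self.width):
            raise ValueError("lesion radius exceeds image size")
        if not (0.0 <= self.label_noise_fraction < 1.0):
            raise ValueError("label_noise_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GaussianSetSpec:
    """Two multivariate-Gaussian classes with optional uniform-box outliers."""

    n_per_class: tuple[int, int] = (100, 100)
    dim: int = 2
    class_means: tuple | None = None
    class_covariances: tuple | None = None
    outlier_fraction: float = 0.0
    seed: int = 0

    def resolved(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self.class_means is None:
            m0 = np.zeros(self.dim)
            m1 = np.zeros(self.dim)
            m1[0] = 2.0
        else:
            m0, m1 = (np.asarray(m, dtype=float) for m in self.class_means)
        if self.class_covariances is None:
            c0 = c1 = np.eye(self.dim)
        else:
            c0, c1 = (np.asarray(c, dtype=float) for c in self.class_covariances)
        for m, c in ((m0, c0), (m1, c1)):
            if m.shape != (self.dim,) or c.shape != (self.dim, self.dim):
                raise ValueError("mean/covariance dimensions do not match dim")
            # positive-definiteness check
            np.linalg.cholesky(c)
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must be in [0, 1)")
        return m0, m1, c0, c1


@dataclass
class Phantom:
    """Generated phantom: three modality stacks plus ROI and label masks.

    ``label_mask`` is +1 on lesion pixels inside the ROI, -1 elsewhere inside
    the ROI, and 0 outside it.
    """

    channels: list[np.ndarray]
    roi_mask: np.ndarray
    label_mask: np.ndarray
    lesion_mask: np.ndarray
    spec: PhantomSpec = field(repr=False, default=None)


def roi_ring_mask(height: int, width: int) -> np.ndarray:
    """Half-annulus band in the lower image half (peripheral-zone stand-in)."""
    rr, cc = np.mgrid[0:height, 0:width]
    cy, cx = 0.42 * height, 0.5 * width
    ry, rx = 0.45 * height, 0.45 * width
    rho = np.sqrt(((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2)
    return (rho >= 0.55) & (rho <= 1.0) & (rr > cy)


def _deformed_ellipse(
    rng: np.random.Generator,
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Random ellipse whose boundary is warped by smoothed noise."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    dy, dx = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / radii[1]
    v = (-sa * dx + ca * dy) / radii[0]
    rho = np.sqrt(u**2 + v**2)
    warp = ndimage.gaussian_filter(rng.standard_normal((H, W)), 3.0)
    warp = 0.35 * warp / (np.abs(warp).max() + 1e-12)
    return rho + warp <= 1.0


def _textured_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    mean: float,
    sigma: float,
    smoothing: float,
) -> np.ndarray:
    """Stationary Gaussian field with given marginal mean/sd and smoothness."""
    noise = rng.standard_normal(shape)
    if smoothing > 0:
        noise = ndimage.gaussian_filter(noise, smoothing)
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return mean + sigma * noise


def _bias_field(
    rng: np.random.Generator, shape: tuple[int, int], amplitude: float
) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude]."""
    if amplitude == 0:
        return np.ones(shape)
    low = rng.standard_normal((4, 4))
    zoomed = ndimage.zoom(low, (shape[0] / 4, shape[1] / 4), order=3)
    zoomed = zoomed[: shape[0], : shape[1]]
    peak = np.abs(zoomed).max()
    return 1.0 + amplitude * zoomed / (peak + 1e-12)


def _place_lesions(
    rng: np.random.Generator, spec: PhantomSpec, roi: np.ndarray
) -> np.ndarray:
    """Disjoint deformed-ellipse lesion masks inside the ROI ring."""
    H, W = roi.shape
    lesions = np.zeros((H, W), dtype=bool)
    candidates = np.argwhere(roi)
    placed, attempts = 0, 0
    max_attempts = 60 * max(1, spec.n_lesions_per_slice)
    lo, hi = spec.lesion_radius_range
    while placed < spec.n_lesions_per_slice and attempts < max_attempts:
        attempts += 1
        cy, cx = candidates[rng.integers(len(candidates))]
        radii = (rng.uniform(lo, hi), rng.uniform(lo, hi))
        blob = _deformed_ellipse(
            rng, (H, W), (float(cy), float(cx)), radii, rng.uniform(0, np.pi)
        )
        blob &= roi
        if blob.sum() < spec.min_lesion_area:
            continue
        if (blob & lesions).any():
            continue
        lesions |= blob
        placed += 1
    return lesions


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate the three-channel phantom with ROI and label masks.

    Channel 0 is the structural (T2-like) channel and carries the configured
    texture contrast; channels 1-2 emulate functional parameter maps with
    half the mean contrast and no autocorrelation difference.  Every slice of
    every channel is corrupted by its own smooth multiplicative bias field
    and a per-slice linear gain/offset.  Identical spec and seed give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    roi = roi_ring_mask(H, W)

    channels = [np.empty((spec.n_slices, H, W)) for _ in range(3)]
    lesion_mask = np.zeros((spec.n_slices, H, W), dtype=bool)
    label_mask = np.zeros((spec.n_slices, H, W), dtype=np.int8)
    contrast = spec.lesion_mean - spec.background_mean

    for z in range(spec.n_slices):
        lesions = _place_lesions(rng, spec, roi)
        lesion_mask[z] = lesions
        # per-channel tissue parameters: (mean_bg, mean_les, smooth_bg, smooth_les)
        params = [
            (
                spec.background_mean,
                spec.lesion_mean,
                spec.background_smoothing_sigma,
                spec.lesion_smoothing_sigma,
            ),
            (
                spec.background_mean,
                spec.background_mean + 0.5 * contrast,
                spec.background_smoothing_sigma,
                spec.background_smoothing_sigma,
            ),
            (
                spec.background_mean,
                spec.background_mean - 0.5 * contrast,
                spec.background_smoothing_sigma,
                spec.background_smoothing_sigma,
            ),
        ]
        for ci, (mb, ml, sb, sl) in enumerate(params):
            bg = _textured_field(rng, (H, W), mb, spec.background_sigma, sb)
            ls = _textured_field(rng, (H, W), ml, spec.lesion_sigma, sl)
            img = np.where(lesions, ls, bg)
            img = img * _bias_field(rng, (H, W), spec.bias_amplitude)
            gain = 1.0 + spec.slice_gain_sigma * rng.standard_normal()
            offset = spec.slice_offset_sigma * rng.standard_normal()
            channels[ci][z] = img * gain + offset

        labels = np.where(lesions, 1, -1).astype(np.int8)
        labels[~roi] = 0
        if spec.label_noise_fraction > 0:
            in_roi = np.argwhere(roi)
            n_flip = int(np.floor(spec.label_noise_fraction * len(in_roi)))
            pick = rng.choice(len(in_roi), size=n_flip, replace=False)
            fr, fc = in_roi[pick].T
            labels[fr, fc] = -labels[fr, fc]
        label_mask[z] = labels

    roi_stack = np.broadcast_to(roi, (spec.n_slices, H, W)).copy()
    return Phantom(
        channels=channels,
        roi_mask=roi_stack,
        label_mask=label_mask,
        lesion_mask=lesion_mask,
        spec=spec,
    )


def generate_gaussian_set(spec: GaussianSetSpec):
    """Draw a labeled two-class Gaussian training set.

    Returns a :class:`pzmap.ensemble.TrainingSet` with labels -1 (class 0)
    and +1 (class 1).  ``outlier_fraction`` of the points of each class are
    redrawn from a wide uniform box spanning six standard deviations around
    the pooled mean, emulating mislabeled or artifact-corrupted pixels.
    """
    from .ensemble import TrainingSet

    m0, m1, c0, c1 = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_class
    X0 = rng.multivariate_normal(m0, c0, size=n0)
    X1 = rng.multivariate_normal(m1, c1, size=n1)

    if spec.outlier_fraction > 0:
        center = (m0 + m1) / 2.0
        span = 6.0 * np.sqrt(
            max(np.diag(c0).max(), np.diag(c1).max())
        ) + np.abs(m1 - m0).max()
        for X, n in ((X0, n0), (X1, n1)):
            n_out = int(np.floor(spec.outlier_fraction * n))
            if n_out:
                idx = rng.choice(n, size=n_out, replace=False)
                X[idx] = rng.uniform(
                    center - span, center + span, size=(n_out, spec.dim)
                )

    X = np.vstack([X0, X1])
    y = np.concatenate([np.full(n0, -1), np.full(n1, 1)])
    return TrainingSet(X=X, y=y, patient_id=np.zeros(n0 + n1, dtype=int))
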