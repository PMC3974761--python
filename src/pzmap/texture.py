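"""Per-pixel texture and intensity features.

Four feature families describe each pixel of the structural channel:

* first-order window statistics — median, standard deviation, third central
  moment, energy and entropy of the empirical value distribution in a small
  square window;
* NGTDM — the neighborhood gray-tone difference matrix: for each gray level
  ``i``, the summed absolute difference between pixels of level ``i`` and the
  mean of their surrounding neighborhood (angular-independent second-order
  texture), condensed into the five Amadasun-King operators (coarseness,
  contrast, busyness, complexity, strength);
* NGLDM — the neighboring gray level dependence matrix: counts of
  ``(gray level, number of similar neighbors)`` pairs under a similarity
  tolerance, condensed into number nonuniformity, second moment and entropy;
* RI-LPQ — rotation-invariant local phase quantization: the signs of the
  imaginary parts of four low-frequency short-term Fourier coefficients,
  evaluated in a per-pixel characteristic-orientation frame and packed into a
  4-bit code, summarized as a local 16-bin code histogram.

The default assembly is 3 raw channel intensities + 5 first-order + 5 NGTDM +
3 NGLDM + 16 RI-LPQ = 32 features per pixel.

Border handling: first-order and RI-LPQ pad the image symmetrically
(edge-mirrored); NGTDM/NGLDM windows use only pixels whose full neighborhood
lies inside the (symmetrically padded) window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

__all__ = [
    "LPQConfig",
    "NGTDMatrix",
    "NGLDMatrix",
    "FeatureStack",
    "TextureConfig",
    "quantize_levels",
    "first_order_features",
    "ngtdm",
    "ngtdm_features",
    "ngtdm_feature_maps",
    "ngldm",
    "ngldm_features",
    "ngldm_feature_maps",
    "rilpq_codes",
    "rilpq_histogram",
    "extract_feature_stack",
]

EPS = 1e-12  # guard for coarseness/strength denominators

FIRST_ORDER_NAMES = ("median", "std", "third_moment", "energy", "entropy")
NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")
NGLDM_NAMES = ("number_nonuniformity", "second_moment", "entropy")


# ---------------------------------------------------------------------------
# containers


@dataclass
class NGTDMatrix:
    """Neighborhood gray-tone difference matrix.

    ``s[i]`` is the summed absolute difference between level-``i`` pixels and
    their neighborhood mean (center excluded); ``p[i]`` the occurrence
    probability of level ``i`` among valid pixels.
    """

    s: np.ndarray
    p: np.ndarray
    n_levels: int
    n_valid: int

    def __post_init__(self) -> None:
        if np.any(self.s[self.p == 0] != 0):
            raise ValueError("s(i) must be 0 wherever p(i) = 0")
        if np.any(self.s < 0):
            raise ValueError("s must be nonnegative")
        if self.n_valid > 0 and abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("p must sum to 1 over levels present")


@dataclass
class NGLDMatrix:
    """Neighboring gray level dependence matrix.

    ``Q[c, r]`` counts pixels of gray level ``c`` having exactly ``r``
    neighbors (within Chebyshev distance ``d``) whose level differs by at
    most the similarity tolerance ``a``.
    """

    Q: np.ndarray
    d: int
    a: float

    def __post_init__(self) -> None:
        if np.any(self.Q < 0):
            raise ValueError("Q entries must be nonnegative")


@dataclass(frozen=True)
class LPQConfig:
    """Configuration of the rotation-invariant LPQ descriptor.

    ``k`` is the (odd) neighborhood side; ``sigma`` the width of the circular
    Gaussian STFT window (default ``k/4``); ``freq_points`` the four
    low-frequency sample points (default the standard LPQ set at radius
    ``1/k``); ``n_angles`` the number of candidate characteristic
    orientations; ``hist_window`` the side of the local code-histogram window.
    """

    k: int = 3
    n_angles: int = 36
    sigma: float | None = None
    freq_points: tuple[tuple[float, float], ...] | None = None
    hist_window: int = 7

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError("k must be odd and >= 3")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.hist_window % 2 == 0:
            raise ValueError("hist_window must be odd")
        if self.freq_points is not None and len(self.freq_points) != 4:
            raise ValueError("exactly four frequency points are required")

    @property
    def sigma_(self) -> float:
        return self.k / 4.0 if self.sigma is None else self.sigma

    @property
    def freq_points_(self) -> np.ndarray:
        if self.freq_points is not None:
            return np.asarray(self.freq_points, dtype=float)
        a = 1.0 / self.k
        return np.array([[a, 0.0], [0.0, a], [a, a], [a, -a]])


@dataclass
class FeatureStack:
    """Per-pixel feature matrix restricted to a mask.

    Rows follow ``pixel_index`` (slice, row, col); ``feature_names`` label the
    columns.  Labels, when attached, are in {-1, +1}.
    """

    X: np.ndarray
    feature_names: list[str]
    pixel_index: np.ndarray
    mask: np.ndarray | None = None
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("FeatureStack contains non-finite values")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    def select(self, indices: list[int] | np.ndarray) -> "FeatureStack":
        idx = np.asarray(indices, dtype=int)
        return FeatureStack(
            X=self.X[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            pixel_index=self.pixel_index,
            mask=self.mask,
            y=self.y,
        )


# ---------------------------------------------------------------------------
# quantization


def quantize_levels(
    image: np.ndarray, n_levels: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Equal-width binning of the masked intensity range into ``n_levels``.

    Returns an integer image with values ``0 .. n_levels-1``; pixels outside
    the masked range are clipped into it.  A constant image maps to all zeros
    with a warning.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    image = np.asarray(image, dtype=float)
    vals = image if mask is None else image[np.asarray(mask, dtype=bool)]
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi == lo:
        warnings.warn("constant image: quantized to all zeros")
        return np.zeros(image.shape, dtype=np.int64)
    scaled = (image - lo) / (hi - lo) * n_levels
    return np.clip(scaled.astype(np.int64), 0, n_levels - 1)


# ---------------------------------------------------------------------------
# first-order window statistics


def _window_rows(image: np.ndarray, w: int) -> np.ndarray:
    """(H*W, w*w) view of symmetric-padded w-windows, row-major pixel order."""
    q = w // 2
    padded = np.pad(np.asarray(image, dtype=float), q, mode="symmetric")
    win = sliding_window_view(padded, (w, w))
    return win.reshape(image.shape[0] * image.shape[1], w * w)


def _run_lengths_sorted(a: np.ndarray) -> np.ndarray:
    """Per-position run length of equal values in row-sorted array ``a``."""
    P, n = a.shape
    idx = np.arange(n)
    change = np.ones_like(a, dtype=bool)
    change[:, 1:] = a[:, 1:] != a[:, :-1]
    run_start = np.maximum.accumulate(np.where(change, idx, 0), axis=1)
    end_change = np.ones_like(change)
    end_change[:, :-1] = change[:, 1:]
    rev = np.where(end_change, idx, n - 1)[:, ::-1]
    run_end = np.minimum.accumulate(rev, axis=1)[:, ::-1]
    return (run_end - run_start + 1).astype(float)


def first_order_features(
    image: np.ndarray, w: int = 5, mask: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Median, std, third central moment, energy and entropy per w-window.

    Energy and entropy are computed from the empirical distribution of the
    exact values in the window (``energy = sum p(z)^2``,
    ``entropy = -sum p(z) log2 p(z)``); the third moment is
    ``sum (z - mean)^3 p(z)``.  Borders are handled by symmetric padding.
    On continuous-valued images energy and entropy degenerate to their
    uniform-distribution constants; feed a quantized image for informative
    values.
    """
    if w % 2 == 0 or w < 3:
        raise ValueError("window must be odd and >= 3")
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    rows = _window_rows(image, w)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        rows = rows[flat_mask]
    n = w * w

    med = np.median(rows, axis=1)
    mean = rows.mean(axis=1)
    centered = rows - mean[:, None]
    var = (centered**2).mean(axis=1)
    std = np.sqrt(var)
    third = (centered**3).mean(axis=1)

    srt = np.sort(rows, axis=1)
    counts = _run_lengths_sorted(srt)
    p_pos = counts / n
    energy = (p_pos / n).sum(axis=1)  # sum over positions of c/n^2 = sum p^2
    entropy = -(np.log2(p_pos) / n).sum(axis=1)

    def full(v: np.ndarray) -> np.ndarray:
        if mask is None:
            return v.reshape(H, W)
        out = np.zeros(H * W)
        out[flat_mask] = v
        return out.reshape(H, W)

    return {
        "median": full(med),
        "std": full(std),
        "third_moment": full(third),
        "energy": full(energy),
        "entropy": full(entropy),
    }


# ---------------------------------------------------------------------------
# NGTDM


def _neighborhood_mean_excl_center(levels: np.ndarray, nbhd: int) -> np.ndarray:
    """Mean over the nbhd x nbhd neighborhood excluding the center pixel."""
    kernel = np.ones((nbhd, nbhd))
    kernel[nbhd // 2, nbhd // 2] = 0.0
    kernel /= kernel.sum()
    return ndimage.correlate(levels.astype(float), kernel, mode="reflect")


def ngtdm(
    image: np.ndarray,
    window: int = 3,
    mask: np.ndarray | None = None,
    n_levels: int | None = None,
) -> NGTDMatrix:
    """NGTDM of a quantized image over a region.

    ``window`` is the (odd) neighborhood side used for the surrounding mean.
    Valid pixels are those whose full neighborhood lies inside the image and,
    if a mask is given, inside the mask.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    levels = np.asarray(image, dtype=np.int64)
    G = int(levels.max()) + 1 if n_levels is None else n_levels
    q = window // 2
    valid = np.zeros(levels.shape, dtype=bool)
    valid[q:-q or None, q:-q or None] = True
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        valid &= ndimage.binary_erosion(
            m, structure=np.ones((window, window)), border_value=0
        )
    if not valid.any():
        raise ValueError("no pixel has a complete neighborhood in the region")

    abar = _neighborhood_mean_excl_center(levels, window)
    lv = levels[valid]
    dv = np.abs(lv - abar[valid])
    s = np.bincount(lv, weights=dv, minlength=G)[:G]
    cnt = np.bincount(lv, minlength=G)[:G]
    return NGTDMatrix(s=s, p=cnt / cnt.sum(), n_levels=G, n_valid=int(cnt.sum()))


def _ngtdm_operators(
    s: np.ndarray, cnt: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Five Amadasun-King operators, vectorized over windows.

    ``s``: (P, G) summed differences; ``cnt``: (P, G) level counts;
    ``n``: (P,) valid pixel counts.  Returns (P, 5).
    """
    p = cnt / n[:, None]
    G = p.shape[1]
    lev = np.arange(G, dtype=float)
    occ = p > 0

    pis = (p * s).sum(axis=1)
    coarseness = 1.0 / (EPS + pis)

    n_occ = occ.sum(axis=1).astype(float)
    e_i = (p * lev).sum(axis=1)
    e_i2 = (p * lev**2).sum(axis=1)
    pair_contrast = 2.0 * (e_i2 - e_i**2)  # sum_ij p_i p_j (i-j)^2
    denom_c = n_occ * (n_occ - 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.where(
            denom_c > 0, pair_contrast / denom_c * (s.sum(axis=1) / n), 0.0
        )

    ip = p * lev[None, :]
    dmat = np.abs(ip[:, :, None] - ip[:, None, :])
    pair_occ = occ[:, :, None] & occ[:, None, :]
    busy_den = np.where(pair_occ, dmat, 0.0).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        busyness = np.where(busy_den > 0, pis / busy_den, 0.0)

    absdiff = np.abs(lev[:, None] - lev[None, :])  # (G, G)
    psum = p[:, :, None] + p[:, None, :]
    ps = p * s
    ps_sum = ps[:, :, None] + ps[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cterm = absdiff[None] / (n[:, None, None] * psum) * ps_sum
    complexity = np.where(pair_occ, cterm, 0.0).sum(axis=(1, 2))

    sterm = psum * absdiff[None] ** 2
    strength = np.where(pair_occ, sterm, 0.0).sum(axis=(1, 2)) / (
        EPS + s.sum(axis=1)
    )
    return np.stack([coarseness, contrast, busyness, complexity, strength], axis=1)


def ngtdm_features(M: NGTDMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength of one NGTDM."""
    cnt = M.p * M.n_valid
    vals = _ngtdm_operators(
        M.s[None, :], cnt[None, :], np.array([float(M.n_valid)])
    )[0]
    return dict(zip(NGTDM_NAMES, (float(v) for v in vals)))


def ngtdm_feature_maps(
    levels: np.ndarray,
    window: int = 9,
    nbhd: int = 3,
    n_levels: int = 32,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel NGTDM operators over a sliding ``window`` x ``window`` patch.

    The matrix of each patch is built from the patch's interior pixels (those
    whose ``nbhd`` neighborhood lies inside the patch); the image is padded
    symmetrically so border pixels get full patches.
    """
    levels = np.asarray(levels, dtype=np.int64)
    H, W = levels.shape
    q, b = window // 2, nbhd // 2
    padded = np.pad(levels, q, mode="symmetric")
    abar = _neighborhood_mean_excl_center(padded, nbhd)
    diff = np.abs(padded - abar)

    lwin = sliding_window_view(padded, (window, window))[:, :, b:-b, b:-b]
    dwin = sliding_window_view(diff, (window, window))[:, :, b:-b, b:-b]
    inner = window - 2 * b
    lrows = lwin.reshape(H * W, inner * inner)
    drows = dwin.reshape(H * W, inner * inner)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        lrows, drows = lrows[flat_mask], drows[flat_mask]
    P, n = lrows.shape
    G = n_levels

    offset = (np.arange(P, dtype=np.int64) * G)[:, None]
    idx = (offset + lrows).ravel()
    s = np.bincount(idx, weights=drows.ravel(), minlength=P * G).reshape(P, G)
    cnt = np.bincount(idx, minlength=P * G).reshape(P, G).astype(float)
    feats = _ngtdm_operators(s, cnt, np.full(P, float(n)))

    out = {}
    for j, name in enumerate(NGTDM_NAMES):
        if mask is None:
            out[name] = feats[:, j].reshape(H, W)
        else:
            full = np.zeros(H * W)
            full[flat_mask] = feats[:, j]
            out[name] = full.reshape(H, W)
    return out


# ---------------------------------------------------------------------------
# NGLDM


def _dependence_counts(levels: np.ndarray, d: int, a: float) -> np.ndarray:
    """Number of neighbors within Chebyshev distance d differing by <= a.

    Computed on the full array; border pixels see only in-array neighbors.
    """
    lv = levels.astype(float)
    H, W = lv.shape
    r = np.zeros((H, W), dtype=np.int64)
    for dr in range(-d, d + 1):
        for dc in range(-d, d + 1):
            if dr == 0 and dc == 0:
                continue
            sr = slice(max(0, dr), min(H, H + dr))
            tr = slice(max(0, -dr), min(H, H - dr))
            sc = slice(max(0, dc), min(W, W + dc))
            tc = slice(max(0, -dc), min(W, W - dc))
            r[tr, tc] += np.abs(lv[sr, sc] - lv[tr, tc]) <= a
    return r


def ngldm(
    image: np.ndarray,
    d: int = 1,
    a: float = 0.0,
    mask: np.ndarray | None = None,
    n_levels: int | None = None,
) -> NGLDMatrix:
    """NGLDM of a quantized image over a region.

    ``Q[c, r]`` counts pixels of level ``c`` with exactly ``r`` neighbors
    within Chebyshev distance ``d`` whose level differs by at most ``a``.
    Valid pixels are those whose full dependence neighborhood lies inside the
    image (and mask, when given).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if a < 0:
        raise ValueError("a must be >= 0")
    levels = np.asarray(image, dtype=np.int64)
    G = int(levels.max()) + 1 if n_levels is None else n_levels
    R = (2 * d + 1) ** 2  # r in 0 .. R-1
    counts = _dependence_counts(levels, d, a)
    valid = np.zeros(levels.shape, dtype=bool)
    valid[d:-d or None, d:-d or None] = True
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        valid &= ndimage.binary_erosion(
            m, structure=np.ones((2 * d + 1, 2 * d + 1)), border_value=0
        )
    if not valid.any():
        raise ValueError("no pixel has a complete neighborhood in the region")
    c, r = levels[valid], counts[valid]
    Q = np.bincount(c * R + r, minlength=G * R).reshape(G, R)
    return NGLDMatrix(Q=Q, d=d, a=a)


def _ngldm_operators(Q: np.ndarray) -> np.ndarray:
    """(number nonuniformity, second moment, entropy) per window, (P, 3)."""
    Ns = Q.sum(axis=(1, 2)).astype(float)
    if np.any(Ns == 0):
        raise ValueError("empty dependence matrix (N_s = 0)")
    nonunif = (Q.sum(axis=1) ** 2).sum(axis=1) / Ns
    second = (Q.astype(float) ** 2).sum(axis=(1, 2)) / Ns
    Pmat = Q / Ns[:, None, None]
    with np.errstate(divide="ignore"):
        logp = np.where(Pmat > 0, np.log2(np.where(Pmat > 0, Pmat, 1.0)), 0.0)
    entropy = -(Pmat * logp).sum(axis=(1, 2))
    return np.stack([nonunif, second, entropy], axis=1)


def ngldm_features(Q: NGLDMatrix) -> dict[str, float]:
    """Number nonuniformity, second moment and entropy of one NGLDM."""
    if Q.Q.sum() == 0:
        raise ValueError("empty dependence matrix (N_s = 0)")
    vals = _ngldm_operators(Q.Q[None].astype(float))[0]
    return dict(zip(NGLDM_NAMES, (float(v) for v in vals)))


def ngldm_feature_maps(
    levels: np.ndarray,
    window: int = 9,
    d: int = 1,
    a: float = 0.0,
    n_levels: int = 32,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-pixel NGLDM operators over a sliding window (symmetric padding)."""
    levels = np.asarray(levels, dtype=np.int64)
    H, W = levels.shape
    q = window // 2
    padded = np.pad(levels, q, mode="symmetric")
    counts = _dependence_counts(padded, d, a)
    R = (2 * d + 1) ** 2
    lwin = sliding_window_view(padded, (window, window))[:, :, d:-d, d:-d]
    rwin = sliding_window_view(counts, (window, window))[:, :, d:-d, d:-d]
    inner = window - 2 * d
    lrows = lwin.reshape(H * W, inner * inner)
    rrows = rwin.reshape(H * W, inner * inner)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        lrows, rrows = lrows[flat_mask], rrows[flat_mask]
    P = lrows.shape[0]
    G = n_levels

    offset = (np.arange(P, dtype=np.int64) * (G * R))[:, None]
    idx = (offset + lrows * R + rrows).ravel()
    Q = np.bincount(idx, minlength=P * G * R).reshape(P, G, R).astype(float)
    feats = _ngldm_operators(Q)

    out = {}
    for j, name in enumerate(NGLDM_NAMES):
        if mask is None:
            out[name] = feats[:, j].reshape(H, W)
        else:
            full = np.zeros(H * W)
            full[flat_mask] = feats[:, j]
            out[name] = full.reshape(H, W)
    return out


# ---------------------------------------------------------------------------
# rotation-invariant LPQ


def _lpq_grid(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Math-convention offset coordinates (x = col offset, y = -row offset)."""
    r = k // 2
    dr, dc = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    return dc.astype(float), (-dr).astype(float)


def _gauss_window(k: int, sigma: float) -> np.ndarray:
    x, y = _lpq_grid(k)
    return np.exp(-(x**2 + y**2) / (2.0 * sigma**2))


def _orientation_kernel(k: int, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """First circular-harmonic kernel (real, imag); center weight zero."""
    x, y = _lpq_grid(k)
    w = _gauss_window(k, sigma)
    phi = np.arctan2(y, x)
    re, im = w * np.cos(phi), w * np.sin(phi)
    c = k // 2
    re[c, c] = im[c, c] = 0.0
    return re, im


def _stft_imag_kernel(k: int, sigma: float, u: np.ndarray) -> np.ndarray:
    """Imaginary part of the windowed STFT kernel at frequency ``u``.

    Antisymmetrized so a constant image yields an exactly zero response.
    """
    x, y = _lpq_grid(k)
    w = _gauss_window(k, sigma)
    im = -w * np.sin(2.0 * np.pi * (u[0] * x + u[1] * y))
    return (im - im[::-1, ::-1]) / 2.0


def rilpq_codes(
    image: np.ndarray, cfg: LPQConfig = LPQConfig(), mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-pixel 4-bit rotation-invariant LPQ codes in {0, ..., 15}.

    A characteristic orientation is estimated per pixel as the phase of the
    first circular-harmonic response, snapped to the nearest of
    ``cfg.n_angles`` candidate angles (ties toward the smaller angle).  The
    four STFT coefficients are evaluated at the frequency points rotated into
    that frame; the sign of each imaginary part (``sign(0) = +``, bit set)
    contributes one bit of the code.
    """
    image = np.asarray(image, dtype=float)
    if mask is not None and np.asarray(mask, dtype=bool).sum() < cfg.k * cfg.k:
        raise ValueError("mask region smaller than the k-neighborhood")
    k, sigma = cfg.k, cfg.sigma_
    n_ang = cfg.n_angles
    freq = cfg.freq_points_

    ore, oim = _orientation_kernel(k, sigma)
    cre = ndimage.correlate(image, ore, mode="reflect")
    cim = ndimage.correlate(image, oim, mode="reflect")
    theta = np.mod(np.arctan2(cim, cre), 2.0 * np.pi)
    step = 2.0 * np.pi / n_ang
    # exact angle ties (common on integer-valued images) are snapped before
    # the ceil so "tie toward the smaller angle" is deterministic under
    # floating-point summation order
    frac = theta / step - 0.5
    near = np.round(frac)
    frac = np.where(np.abs(frac - near) <= 1e-9, near, frac)
    ang_idx = np.mod(np.ceil(frac).astype(np.int64), n_ang)
    # sign deadzone: responses within tol of 0 count as 0 (bit set)
    tol = 1e-9 * max(1.0, float(np.abs(image).max()))

    codes = np.zeros(image.shape, dtype=np.int64)
    for a_i in range(n_ang):
        sel = ang_idx == a_i
        if not sel.any():
            continue
        th = a_i * step
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        code_a = np.zeros(image.shape, dtype=np.int64)
        for j in range(4):
            u = rot @ freq[j]
            imresp = ndimage.correlate(
                image, _stft_imag_kernel(k, sigma, u), mode="reflect"
            )
            code_a |= (imresp >= -tol).astype(np.int64) << j
        codes[sel] = code_a[sel]
    return codes


def rilpq_histogram(
    codes: np.ndarray, hist_window: int = 7, mask: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Normalized 16-bin histogram of LPQ codes in a local window, per pixel."""
    if hist_window % 2 == 0:
        raise ValueError("hist_window must be odd")
    codes = np.asarray(codes, dtype=np.int64)
    H, W = codes.shape
    rows = _window_rows(codes, hist_window).astype(np.int64)
    if mask is not None:
        flat_mask = np.asarray(mask, dtype=bool).ravel()
        rows = rows[flat_mask]
    P, n = rows.shape
    offset = (np.arange(P, dtype=np.int64) * 16)[:, None]
    hist = np.bincount((offset + rows).ravel(), minlength=P * 16).reshape(P, 16)
    hist = hist / n
    out = {}
    for b in range(16):
        name = f"lpq_{b:02d}"
        if mask is None:
            out[name] = hist[:, b].reshape(H, W)
        else:
            full = np.zeros(H * W)
            full[flat_mask] = hist[:, b]
            out[name] = full.reshape(H, W)
    return out


# ---------------------------------------------------------------------------
# feature-stack assembly


@dataclass(frozen=True)
class TextureConfig:
    """Configuration of the default 32-column feature stack.

    ``ngldm_a`` is the similarity tolerance expressed on the standard scale
    ``[s1, s2]``; it is converted to gray-level units as
    ``a * n_levels / (s2 - s1)`` so its meaning survives z-scoring.  An
    optional second first-order window adds five more columns.
    """

    first_order_window: int = 5
    first_order_window2: int | None = None
    n_levels: int = 32
    ngtdm_window: int = 9
    ngtdm_nbhd: int = 3
    ngldm_window: int = 9
    ngldm_d: int = 1
    ngldm_a: float = 10.0
    scale_range: float = 4094.0  # s2 - s1 of the standard scale
    lpq: LPQConfig = field(default_factory=LPQConfig)
    include_functional: bool = True
    include_texture: bool = True

    @property
    def ngldm_a_levels(self) -> float:
        return self.ngldm_a * self.n_levels / self.scale_range


CHANNEL_NAMES = ("t2", "mtt", "pf")


def extract_feature_stack(
    stacks: list[np.ndarray],
    mask: np.ndarray,
    config: TextureConfig = TextureConfig(),
    labels: np.ndarray | None = None,
) -> FeatureStack:
    """Assemble the per-pixel feature matrix over the masked region.

    ``stacks`` holds up to three co-registered (n_slices, H, W) modality
    arrays; texture is computed from the first (structural) channel only.
    First-order median/std/third-moment come from the continuous intensities;
    energy/entropy and the NGTDM/NGLDM operators from the gray-level
    quantized channel.  The default configuration yields 32 columns.
    """
    stacks = [np.asarray(s, dtype=float) for s in stacks]
    shape = stacks[0].shape
    for s in stacks[1:]:
        if s.shape != shape:
            raise ValueError("modality stacks must share identical geometry")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask geometry must match the stacks")
    if labels is not None and np.asarray(labels).shape != shape:
        raise ValueError("label geometry must match the stacks")

    n_slices = shape[0]
    cols: dict[str, list[np.ndarray]] = {}
    index_parts = []
    label_parts = []

    use_channels = stacks if config.include_functional else stacks[:1]
    names: list[str] = list(CHANNEL_NAMES[: len(use_channels)])

    fo_windows = [config.first_order_window]
    if config.first_order_window2 is not None:
        fo_windows.append(config.first_order_window2)
    if config.include_texture:
        for w in fo_windows:
            suffix = "" if len(fo_windows) == 1 else f"_w{w}"
            names += [f"fo_{nm}{suffix}" for nm in FIRST_ORDER_NAMES]
        names += [f"ngtdm_{nm}" for nm in NGTDM_NAMES]
        names += [f"ngldm_{nm}" for nm in NGLDM_NAMES]
        names += [f"lpq_{b:02d}" for b in range(16)]
    for nm in names:
        cols[nm] = []

    for z in range(n_slices):
        m = mask[z]
        if not m.any():
            continue
        for ci, stack in enumerate(use_channels):
            cols[CHANNEL_NAMES[ci]].append(stack[z][m])
        if config.include_texture:
            t2 = stacks[0][z]
            levels = quantize_levels(t2, config.n_levels, mask=m)
            for w in fo_windows:
                suffix = "" if len(fo_windows) == 1 else f"_w{w}"
                fo_cont = first_order_features(t2, w=w, mask=m)
                fo_quant = first_order_features(levels, w=w, mask=m)
                for nm in ("median", "std", "third_moment"):
                    cols[f"fo_{nm}{suffix}"].append(fo_cont[nm][m])
                for nm in ("energy", "entropy"):
                    cols[f"fo_{nm}{suffix}"].append(fo_quant[nm][m])
            ngt = ngtdm_feature_maps(
                levels,
                window=config.ngtdm_window,
                nbhd=config.ngtdm_nbhd,
                n_levels=config.n_levels,
                mask=m,
            )
            for nm in NGTDM_NAMES:
                cols[f"ngtdm_{nm}"].append(ngt[nm][m])
            ngl = ngldm_feature_maps(
                levels,
                window=config.ngldm_window,
                d=config.ngldm_d,
                a=config.ngldm_a_levels,
                n_levels=config.n_levels,
                mask=m,
            )
            for nm in NGLDM_NAMES:
                cols[f"ngldm_{nm}"].append(ngl[nm][m])
            codes = rilpq_codes(t2, cfg=config.lpq)
            hist = rilpq_histogram(codes, hist_window=config.lpq.hist_window, mask=m)
            for b in range(16):
                cols[f"lpq_{b:02d}"].append(hist[f"lpq_{b:02d}"][m])
        rr, cc = np.nonzero(m)
        index_parts.append(
            np.column_stack([np.full(rr.size, z, dtype=np.int64), rr, cc])
        )
        if labels is not None:
            label_parts.append(np.asarray(labels)[z][m])

    X = np.column_stack([np.concatenate(cols[nm]) for nm in names])
    return FeatureStack(
        X=X,
        feature_names=names,
        pixel_index=np.concatenate(index_parts),
        mask=mask,
        y=np.concatenate(label_parts).astype(int) if labels is not None else None,
    )
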