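"""Naive per-pixel reimplementations of the texture operators.

Every function here recomputes a feature with explicit Python loops and no
shared code with the package implementation; the test suite checks the two
routes agree (exactly for integer codes and counts, to tight relative
tolerance for real-valued features).
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-12


def pad_symmetric(image: np.ndarray, q: int) -> np.ndarray:
    return np.pad(image, q, mode="symmetric")


def first_order_window(vals: np.ndarray) -> tuple[float, float, float, float, float]:
    """Median, std, third central moment, energy, entropy of one window."""
    vals = np.asarray(vals, dtype=float).ravel()
    n = vals.size
    med = float(np.median(vals))
    mean = vals.mean()
    std = math.sqrt(((vals - mean) ** 2).mean())
    third = ((vals - mean) ** 3).mean()
    uniq, counts = np.unique(vals, return_counts=True)
    p = counts / n
    energy = float((p**2).sum())
    entropy = float(-(p * np.log2(p)).sum())
    return med, std, third, energy, entropy


def first_order_maps(image: np.ndarray, w: int) -> np.ndarray:
    H, W = image.shape
    q = w // 2
    padded = pad_symmetric(image, q)
    out = np.zeros((5, H, W))
    for r in range(H):
        for c in range(W):
            win = padded[r : r + w, c : c + w]
            out[:, r, c] = first_order_window(win)
    return out


def ngtdm_region(levels: np.ndarray, window: int, n_levels: int):
    """(s, p, n_valid) of the NGTDM over the whole (unpadded) image."""
    H, W = levels.shape
    q = window // 2
    s = np.zeros(n_levels)
    cnt = np.zeros(n_levels, dtype=int)
    for r in range(q, H - q):
        for c in range(q, W - q):
            nb = levels[r - q : r + q + 1, c - q : c + q + 1].astype(float)
            total = nb.sum() - levels[r, c]
            abar = total / (window * window - 1)
            i = int(levels[r, c])
            s[i] += abs(i - abar)
            cnt[i] += 1
    n = cnt.sum()
    return s, cnt / n, int(n)


def ngtdm_operators(s: np.ndarray, p: np.ndarray, n: int) -> tuple:
    """The five operators from (s, p) by direct double loops."""
    G = len(p)
    occupied = [i for i in range(G) if p[i] > 0]
    pis = sum(p[i] * s[i] for i in range(G))
    coarseness = 1.0 / (EPS + pis)

    Np = len(occupied)
    pair = sum(
        p[i] * p[j] * (i - j) ** 2 for i in range(G) for j in range(G)
    )
    contrast = (
        pair / (Np * (Np - 1)) * (s.sum() / n) if Np > 1 else 0.0
    )

    busy_den = sum(
        abs(i * p[i] - j * p[j]) for i in occupied for j in occupied
    )
    busyness = pis / busy_den if busy_den > 0 else 0.0

    complexity = sum(
        abs(i - j) / (n * (p[i] + p[j])) * (p[i] * s[i] + p[j] * s[j])
        for i in occupied
        for j in occupied
    )
    strength = sum(
        (p[i] + p[j]) * (i - j) ** 2 for i in occupied for j in occupied
    ) / (EPS + s.sum())
    return coarseness, contrast, busyness, complexity, strength


def ngtdm_maps(levels: np.ndarray, window: int, nbhd: int, n_levels: int) -> np.ndarray:
    """Per-pixel sliding-window NGTDM features, symmetric padding."""
    H, W = levels.shape
    q = window // 2
    padded = pad_symmetric(levels, q)
    out = np.zeros((5, H, W))
    for r in range(H):
        for c in range(W):
            win = padded[r : r + window, c : c + window]
            s, p, n = ngtdm_region(win, nbhd, n_levels)
            out[:, r, c] = ngtdm_operators(s, p, n)
    return out


def ngldm_region(levels: np.ndarray, d: int, a: float, n_levels: int) -> np.ndarray:
    H, W = levels.shape
    R = (2 * d + 1) ** 2
    Q = np.zeros((n_levels, R), dtype=int)
    for r in range(d, H - d):
        for c in range(d, W - d):
            deps = 0
            for dr in range(-d, d + 1):
                for dc in range(-d, d + 1):
                    if dr == 0 and dc == 0:
                        continue
                    if abs(float(levels[r + dr, c + dc]) - float(levels[r, c])) <= a:
                        deps += 1
            Q[int(levels[r, c]), deps] += 1
    return Q


def ngldm_operators(Q: np.ndarray) -> tuple[float, float, float]:
    Ns = Q.sum()
    nonunif = sum(Q[:, r].sum() ** 2 for r in range(Q.shape[1])) / Ns
    second = (Q.astype(float) ** 2).sum() / Ns
    entropy = 0.0
    for v in Q.ravel():
        if v > 0:
            entropy -= (v / Ns) * math.log2(v / Ns)
    return float(nonunif), float(second), float(entropy)


def ngldm_maps(
    levels: np.ndarray, window: int, d: int, a: float, n_levels: int
) -> np.ndarray:
    H, W = levels.shape
    q = window // 2
    padded = pad_symmetric(levels, q)
    out = np.zeros((3, H, W))
    for r in range(H):
        for c in range(W):
            win = padded[r : r + window, c : c + window]
            out[:, r, c] = ngldm_operators(ngldm_region(win, d, a, n_levels))
    return out


# --- RI-LPQ -----------------------------------------------------------------


def _lpq_coords(k: int):
    r = k // 2
    coords = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            coords.append((dr, dc, float(dc), float(-dr)))  # x=dc, y=-dr
    return coords


def rilpq_code_at(
    padded: np.ndarray, r: int, c: int, k: int, sigma: float,
    freq: np.ndarray, n_angles: int, tol: float = 0.0,
) -> int:
    """One pixel's code: orientation estimate then 4 STFT imaginary signs."""
    coords = _lpq_coords(k)
    # characteristic orientation from the first circular harmonic
    acc = 0.0 + 0.0j
    for dr, dc, x, y in coords:
        if dr == 0 and dc == 0:
            continue
        w = math.exp(-(x * x + y * y) / (2 * sigma * sigma))
        phi = math.atan2(y, x)
        acc += padded[r + dr, c + dc] * w * complex(math.cos(phi), math.sin(phi))
    theta = math.atan2(acc.imag, acc.real) % (2 * math.pi)
    step = 2 * math.pi / n_angles
    frac = theta / step - 0.5
    near = round(frac)
    if abs(frac - near) <= 1e-9:
        frac = near
    idx = int(math.ceil(frac)) % n_angles
    th = idx * step

    code = 0
    for j in range(4):
        ux = math.cos(th) * freq[j][0] - math.sin(th) * freq[j][1]
        uy = math.sin(th) * freq[j][0] + math.cos(th) * freq[j][1]
        im = 0.0
        for dr, dc, x, y in coords:
            w = math.exp(-(x * x + y * y) / (2 * sigma * sigma))
            # antisymmetrized imaginary kernel, matching the convention that
            # a constant image gives an exactly zero response
            v1 = -w * math.sin(2 * math.pi * (ux * x + uy * y))
            v2 = -w * math.sin(2 * math.pi * (ux * (-x) + uy * (-y)))
            im += padded[r + dr, c + dc] * (v1 - v2) / 2.0
        if im >= -tol:
            code |= 1 << j
    return code


def rilpq_code_map(
    image: np.ndarray, k: int, sigma: float, freq: np.ndarray, n_angles: int
) -> np.ndarray:
    H, W = image.shape
    q = k // 2
    padded = pad_symmetric(image.astype(float), q)
    tol = 1e-9 * max(1.0, float(np.abs(image).max()))
    out = np.zeros((H, W), dtype=int)
    for r in range(H):
        for c in range(W):
            out[r, c] = rilpq_code_at(
                padded, r + q, c + q, k, sigma, freq, n_angles, tol
            )
    return out


def rilpq_hist_maps(codes: np.ndarray, hist_window: int) -> np.ndarray:
    H, W = codes.shape
    q = hist_window // 2
    padded = pad_symmetric(codes, q)
    out = np.zeros((16, H, W))
    n = hist_window * hist_window
    for r in range(H):
        for c in range(W):
            win = padded[r : r + hist_window, c : c + hist_window].ravel()
            for b in range(16):
                out[b, r, c] = np.sum(win == b) / n
    return out


def roc_auc_pairs(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive positive-negative pair counting (half credit ties)."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
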