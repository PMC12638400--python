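"""Independent brute-force oracles used to validate the fast implementations.

Every function here evaluates the defining formula directly (explicit loops,
pairwise enumeration), sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def gaussian_window(sigma: float = 1.5, radius: int = 5) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    return np.outer(k, k)


def ssim_sliding_window(im: np.ndarray, ref: np.ndarray, data_range: float = 1.0,
                        k1: float = 0.01, k2: float = 0.03) -> float:
    """Per-pixel 11x11 Gaussian-window evaluation of the SSIM formula.

    Edge-padded windows; the mean excludes the window-radius border, matching
    the filtered implementation's averaging region.
    """
    radius = 5
    w = gaussian_window(1.5, radius)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    imp = np.pad(im.astype(float), radius, mode="edge")
    rfp = np.pad(ref.astype(float), radius, mode="edge")
    h, wdt = im.shape
    smap = np.empty((h, wdt))
    for i in range(h):
        for j in range(wdt):
            a = imp[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            b = rfp[i:i + 2 * radius + 1, j:j + 2 * radius + 1]
            mu1 = (w * a).sum()
            mu2 = (w * b).sum()
            s11 = (w * a * a).sum() - mu1 * mu1
            s22 = (w * b * b).sum() - mu2 * mu2
            s12 = (w * a * b).sum() - mu1 * mu2
            smap[i, j] = ((2 * mu1 * mu2 + c1) * (2 * s12 + c2)
                          / ((mu1 ** 2 + mu2 ** 2 + c1) * (s11 + s22 + c2)))
    return float(smap[radius:h - radius, radius:wdt - radius].mean())


def gradient_loops(sl: np.ndarray) -> np.ndarray:
    """Gradient magnitude by explicit centred/one-sided differences."""
    h, w = sl.shape
    g = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            if 0 < i < h - 1:
                gy = (sl[i + 1, j] - sl[i - 1, j]) / 2.0
            elif i == 0:
                gy = sl[1, j] - sl[0, j]
            else:
                gy = sl[h - 1, j] - sl[h - 2, j]
            if 0 < j < w - 1:
                gx = (sl[i, j + 1] - sl[i, j - 1]) / 2.0
            elif j == 0:
                gx = sl[i, 1] - sl[i, 0]
            else:
                gx = sl[i, w - 1] - sl[i, w - 2]
            g[i, j] = math.sqrt(gx * gx + gy * gy)
    return g


def tenengrad_loops(sl: np.ndarray) -> float:
    g = gradient_loops(sl)
    total = 0.0
    for v in g.ravel():
        total += v * v
    return total / g.size


def ngs_loops(sl: np.ndarray) -> float:
    g = gradient_loops(sl)
    s = float(g.sum())
    total = 0.0
    for v in g.ravel():
        total += (v / s) ** 2
    return total


def image_entropy_loops(sl: np.ndarray) -> float:
    energy = float((sl.astype(float) ** 2).sum())
    total = 0.0
    for v in sl.ravel():
        y = v / math.sqrt(energy)
        if y > 0:
            total -= y * math.log(y)
    return total


def gradient_entropy_loops(sl: np.ndarray) -> float:
    g = gradient_loops(sl)
    energy = float((g ** 2).sum())
    total = 0.0
    for v in g.ravel():
        z = v / math.sqrt(energy)
        if z > 0:
            total -= z * math.log(z)
    return total


def midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks computed by counting, not sorting library calls."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.size)
    for i, v in enumerate(x):
        smaller = int((x < v).sum())
        ties = int((x == v).sum())
        out[i] = smaller + (ties + 1) / 2.0
    return out


def spearman_rho_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks, evaluated from the definition."""
    rx, ry = midranks(np.asarray(x)), midranks(np.asarray(y))
    mx, my = rx.mean(), ry.mean()
    num = float(((rx - mx) * (ry - my)).sum())
    den = math.sqrt(float(((rx - mx) ** 2).sum()) * float(((ry - my) ** 2).sum()))
    return num / den


def krippendorff_oracle(scores: np.ndarray, level: str = "ordinal") -> float:
    """Alpha by explicit enumeration of all pairable value pairs.

    D_o sums disagreements over every ordered within-unit pair, weighted by
    1/(m_u - 1); D_e over every ordered pair of pairable ratings.
    """
    units = [row[np.isfinite(row)] for row in np.asarray(scores, dtype=float)]
    units = [u for u in units if u.size >= 2]
    values = np.unique(np.concatenate(units))
    pooled = np.concatenate(units)
    n = pooled.size

    counts = {v: int((pooled == v).sum()) for v in values}

    def delta(a: float, b: float) -> float:
        if a == b:
            return 0.0
        if level == "nominal":
            return 1.0
        if level == "interval":
            return (a - b) ** 2
        lo, hi = min(a, b), max(a, b)
        between = sum(counts[v] for v in values if lo <= v <= hi)
        return (between - (counts[lo] + counts[hi]) / 2.0) ** 2

    d_obs = 0.0
    for u in units:
        m = u.size
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_obs += delta(u[i], u[j]) / (m - 1)
    d_obs /= n

    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += delta(pooled[i], pooled[j])
    d_exp /= n * (n - 1)
    return 1.0 - d_obs / d_exp
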