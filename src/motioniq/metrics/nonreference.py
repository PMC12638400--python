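"""Reference-free slice-wise metrics: TG, AES, NGS, IE, GE.

All five are sharpness/structure measures built on the pixel intensities
``x_ij`` and the gradient magnitude ``g_ij = sqrt(gx^2 + gy^2)``:

* ``TG``  (Tenengrad)           -- mean of ``g^2``; higher = sharper.
* ``AES`` (average edge strength) -- ``sqrt(sum_E g^2) / |E|`` over a binary
  edge mask ``E``; higher = sharper.
* ``NGS`` (normalised gradient squared) -- ``sum (g / sum g)^2``, a
  scale-invariant version of TG; higher = sharper.
* ``IE``  (image entropy)       -- ``-sum y ln y`` with ``y = x / sqrt(sum x^2)``;
  lower = more ordered intensities = better.
* ``GE``  (gradient entropy)    -- the same functional on ``g``; lower = more
  concentrated edges = better.

Gradients are centred finite differences in the interior and one-sided at
the borders.  Under a restricted evaluation domain the gradients are
computed on the full slice first and masked afterwards, so the domain
boundary does not inject artificial edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import feature

from ..volume import DegenerateVolumeError, SlicePair
from .base import Direction, MetricSpec, register

__all__ = [
    "GradientField",
    "gradient_magnitude",
    "tenengrad",
    "aes",
    "ngs",
    "image_entropy",
    "gradient_entropy",
]


@dataclass
class GradientField:
    gx: np.ndarray
    gy: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.gx ** 2 + self.gy ** 2)


def gradient_magnitude(slice_: np.ndarray) -> GradientField:
    """Directional derivatives of a 2D slice (centred interior, one-sided borders)."""
    arr = np.asarray(slice_, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise ValueError("slice must be 2D with every dimension >= 3")
    gy, gx = np.gradient(arr)
    return GradientField(gx=gx, gy=gy)


def _domain_values(arr: np.ndarray, domain: Optional[np.ndarray]) -> np.ndarray:
    return arr.ravel() if domain is None else arr[domain]


def tenengrad(pair: SlicePair) -> float:
    """Mean squared gradient magnitude over the evaluation domain."""
    g = gradient_magnitude(pair.image).magnitude
    vals = _domain_values(g, pair.domain)
    if vals.size == 0:
        raise DegenerateVolumeError("empty evaluation domain")
    return float(np.mean(vals ** 2))


def aes(pair: SlicePair, canny_sigma: float = 2.0,
        low_quantile: float = 0.70, high_quantile: float = 0.90) -> float:
    """Average edge strength over a detected edge mask.

    Edges come from a Canny detector (Gaussian sigma 2, hysteresis
    thresholds at the 70th/90th gradient-magnitude quantiles).  The value is
    ``sqrt(sum_E g^2) / |E|``.  Returns NaN (missing) when no edges are
    detected, e.g. on a featureless slice; the slice is then excluded from
    the reduction.
    """
    im = pair.image
    if np.ptp(im) == 0:
        return float("nan")
    # hysteresis thresholds from the quantiles of the *positive* smoothed
    # gradient magnitudes: on background-zeroed images most pixels have
    # exactly zero gradient, which would otherwise collapse the quantiles
    from scipy import ndimage as ndi
    sm = ndi.gaussian_filter(im, canny_sigma)
    mag = np.hypot(ndi.sobel(sm, axis=0), ndi.sobel(sm, axis=1))
    pos = mag[mag > 0]
    if pos.size == 0:
        return float("nan")
    low, high = np.quantile(pos, (low_quantile, high_quantile))
    edges = feature.canny(im, sigma=canny_sigma, low_threshold=low,
                          high_threshold=high)
    if pair.domain is not None:
        edges = edges & pair.domain
    n_edges = int(edges.sum())
    if n_edges == 0:
        return float("nan")
    g = gradient_magnitude(im).magnitude
    return float(np.sqrt(np.sum(g[edges] ** 2)) / n_edges)


def ngs(pair: SlicePair) -> float:
    """Normalised gradient squared: ``sum g^2 / (sum g)^2``; in (0, 1]."""
    g = gradient_magnitude(pair.image).magnitude
    vals = _domain_values(g, pair.domain)
    total = float(vals.sum())
    if total == 0.0:
        return float("nan")
    return float(np.sum(vals ** 2) / total ** 2)


def _entropy_of(vals: np.ndarray, what: str) -> float:
    """``-sum v ln v`` with ``v = |x| / sqrt(sum x^2)``; 0 ln 0 := 0."""
    energy = float(np.sum(vals ** 2))
    if energy == 0.0:
        raise DegenerateVolumeError(f"all-zero {what}: entropy undefined")
    y = np.abs(vals) / np.sqrt(energy)
    y = y[y > 0]
    return float(-np.sum(y * np.log(y)))


def image_entropy(pair: SlicePair) -> float:
    """Entropy of energy-normalised intensities (nats); lower = better."""
    vals = _domain_values(pair.image, pair.domain)
    return _entropy_of(vals, "intensities")


def gradient_entropy(pair: SlicePair) -> float:
    """Entropy of energy-normalised gradient magnitudes (nats); lower = better."""
    g = gradient_magnitude(pair.image).magnitude
    vals = _domain_values(g, pair.domain)
    return _entropy_of(vals, "gradient field")


register(MetricSpec("TG", Direction.HIGHER_BETTER, False, "any", tenengrad))
register(MetricSpec("AES", Direction.HIGHER_BETTER, False, "any", aes))
register(MetricSpec("NGS", Direction.HIGHER_BETTER, False, "any", ngs))
register(MetricSpec("IE", Direction.LOWER_BETTER, False, "any", image_entropy))
register(MetricSpec("GE", Direction.LOWER_BETTER, False, "any", gradient_entropy))
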