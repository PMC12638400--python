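"""Full-reference slice-wise quality metrics: SSIM, PSNR, FSIM, VIF.

SSIM and PSNR accept any intensity range (SSIM's stabilising constants scale
with the dynamic range L).  FSIM and VIF carry constants calibrated for
8-bit natural images, so they demand inputs in [0, 1] (internally mapped to
[0, 255]) or [0, 255], and they operate on the full rectangular grid --
restricting their evaluation domain to an irregular brain-mask region is
rejected, because both are defined through neighbourhood filtering of the
whole matrix.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from scipy import ndimage

from ..volume import DegenerateVolumeError, SlicePair
from .base import (Direction, MetricDomainError, MetricSpec, check_value_range,
                   register)

__all__ = ["ssim", "psnr", "fsim", "vif", "phase_congruency"]

_EPS = 1e-12


# --------------------------------------------------------------------------
# SSIM
# --------------------------------------------------------------------------

def _gaussian_kernel1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _ssim_map(im: np.ndarray, ref: np.ndarray, data_range: float,
              k1: float, k2: float, window: str) -> tuple[np.ndarray, int]:
    """Local SSIM map and the border pad excluded from averaging.

    Filtering uses edge ('nearest') padding; the pad-wide border, where the
    window hangs off the image, is excluded from the mean.
    """
    if window == "gaussian_11_sigma1.5":
        radius = 5
        kern = _gaussian_kernel1d(1.5, radius)
        kern2d = np.outer(kern, kern)

        def filt(a: np.ndarray) -> np.ndarray:
            return ndimage.correlate(a, kern2d, mode="nearest")
    elif window == "uniform_7":
        radius = 3

        def filt(a: np.ndarray) -> np.ndarray:
            return ndimage.uniform_filter(a, size=7, mode="nearest")
    else:
        raise ValueError(f"unknown SSIM window {window!r}")

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu1, mu2 = filt(im), filt(ref)
    s11 = filt(im * im) - mu1 * mu1
    s22 = filt(ref * ref) - mu2 * mu2
    s12 = filt(im * ref) - mu1 * mu2
    num = (2 * mu1 * mu2 + c1) * (2 * s12 + c2)
    den = (mu1 * mu1 + mu2 * mu2 + c1) * (s11 + s22 + c2)
    return num / den, radius


def ssim(pair: SlicePair, window: str = "gaussian_11_sigma1.5",
         k1: float = 0.01, k2: float = 0.03,
         data_range: Optional[float] = None) -> float:
    """Structural similarity index between a slice and its reference.

    Windowed means/variances/covariance enter the familiar luminance x
    contrast/structure product; the map is averaged over the evaluation
    domain.  Defaults: 11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03.
    The dynamic range L defaults to 1 for unit-range inputs and to the
    reference's max-min otherwise.
    """
    im, ref = pair.image, pair.reference
    if ref is None:
        raise MetricDomainError("SSIM requires a reference slice")
    if data_range is None:
        hi = max(im.max(), ref.max())
        lo = min(im.min(), ref.min())
        if lo >= -1e-9 and hi <= 1 + 1e-9:
            data_range = 1.0
        else:
            data_range = float(ref.max() - ref.min())
            if data_range == 0:
                raise DegenerateVolumeError("constant reference slice: L undefined")
    smap, pad = _ssim_map(im, ref, data_range, k1, k2, window)
    inner = (slice(pad, smap.shape[0] - pad), slice(pad, smap.shape[1] - pad))
    if pair.domain is None:
        return float(smap[inner].mean())
    dom = pair.domain[inner]
    if not dom.any():
        raise MetricDomainError("empty evaluation domain for SSIM")
    return float(smap[inner][dom].mean())


# --------------------------------------------------------------------------
# PSNR
# --------------------------------------------------------------------------

def psnr(pair: SlicePair) -> float:
    """Peak signal-to-noise ratio in dB, with the peak taken on the reference.

    Identical inputs have zero mean-squared error; the +inf sentinel is
    returned and later excluded from correlations.
    """
    im, ref = pair.image, pair.reference
    if ref is None:
        raise MetricDomainError("PSNR requires a reference slice")
    if pair.domain is not None:
        if not pair.domain.any():
            raise MetricDomainError("empty evaluation domain for PSNR")
        im, ref = im[pair.domain], ref[pair.domain]
    mse = float(np.mean((im - ref) ** 2))
    if mse == 0.0:
        return math.inf
    peak = float(np.max(ref))
    if peak <= 0:
        raise DegenerateVolumeError("non-positive reference peak")
    return float(10.0 * math.log10(peak ** 2 / mse))


# --------------------------------------------------------------------------
# FSIM -- phase-congruency + gradient-magnitude feature similarity
# --------------------------------------------------------------------------

_PC_CACHE: dict = {}


def _pc_filters(shape: tuple[int, int], nscale: int, norient: int,
                min_wavelength: float, mult: float, sigma_onf: float,
                dtheta_sigma: float) -> list[list[np.ndarray]]:
    """Log-Gabor x angular-spread frequency-domain filter bank (cached)."""
    key = (shape, nscale, norient, min_wavelength, mult, sigma_onf, dtheta_sigma)
    if key in _PC_CACHE:
        return _PC_CACHE[key]
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx ** 2 + fy ** 2)
    radius[0, 0] = 1.0  # avoid log(0) at DC; the filter is zeroed there anyway
    theta = np.arctan2(-fy, fx)
    sintheta, costheta = np.sin(theta), np.cos(theta)

    lowpass = 1.0 / (1.0 + (radius / 0.45) ** (2 * 15))
    log_gabors = []
    for s in range(nscale):
        f0 = 1.0 / (min_wavelength * mult ** s)
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2 * math.log(sigma_onf) ** 2))
        lg *= lowpass
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = math.pi / norient / dtheta_sigma
    spreads = []
    for o in range(norient):
        angl = o * math.pi / norient
        ds = sintheta * math.cos(angl) - costheta * math.sin(angl)
        dc = costheta * math.cos(angl) + sintheta * math.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta ** 2) / (2 * theta_sigma ** 2)))

    bank = [[lg * sp for lg in log_gabors] for sp in spreads]
    _PC_CACHE[key] = bank
    return bank


def phase_congruency(im: np.ndarray, nscale: int = 4, norient: int = 4,
                     min_wavelength: float = 6.0, mult: float = 2.0,
                     sigma_onf: float = 0.55, k: float = 2.0,
                     cutoff: float = 0.5, g: float = 10.0,
                     dtheta_sigma: float = 1.2) -> np.ndarray:
    """Phase congruency map of a 2D image via a log-Gabor quadrature bank.

    Fourier components that are maximally in phase mark perceptually salient
    features (edges, lines) independently of local contrast.  Per
    orientation, local energy is computed from the quadrature filter
    responses, an estimated Rayleigh noise floor is subtracted, and a
    frequency-spread sigmoid down-weights responses supported by a single
    scale; orientations are combined by summing energy and normalising by
    the summed response amplitudes.
    """
    im = np.asarray(im, dtype=np.float64)
    bank = _pc_filters(im.shape, nscale, norient, min_wavelength, mult,
                       sigma_onf, dtheta_sigma)
    imfft = np.fft.fft2(im)
    energy_all = np.zeros(im.shape)
    an_all = np.zeros(im.shape)
    for o in range(norient):
        eo = [np.fft.ifft2(imfft * bank[o][s]) for s in range(nscale)]
        an = [np.abs(e) for e in eo]
        sum_an = np.sum(an, axis=0)
        sum_e = np.sum([e.real for e in eo], axis=0)
        sum_o = np.sum([e.imag for e in eo], axis=0)
        x_energy = np.sqrt(sum_e ** 2 + sum_o ** 2) + _EPS
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros(im.shape)
        for e in eo:
            energy += e.real * mean_e + e.imag * mean_o \
                - np.abs(e.real * mean_o - e.imag * mean_e)
        # Rayleigh noise floor estimated from the smallest-scale amplitudes
        tau = np.median(an[0]) / math.sqrt(math.log(4))
        total_tau = tau * (1 - (1 / mult) ** nscale) / (1 - 1 / mult)
        noise_mean = total_tau * math.sqrt(math.pi / 2)
        noise_sigma = total_tau * math.sqrt((4 - math.pi) / 2)
        energy = np.maximum(energy - (noise_mean + k * noise_sigma), 0.0)
        max_an = np.max(an, axis=0)
        width = (sum_an / (max_an + _EPS) - 1) / (nscale - 1)
        weight = 1.0 / (1.0 + np.exp(g * (cutoff - width)))
        energy_all += weight * energy
        an_all += sum_an
    return energy_all / (an_all + _EPS)


_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], dtype=np.float64) / 16.0


def _scharr_magnitude(im: np.ndarray) -> np.ndarray:
    gx = ndimage.convolve(im, _SCHARR_X, mode="nearest")
    gy = ndimage.convolve(im, _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx ** 2 + gy ** 2)


def fsim(pair: SlicePair, t1: float = 0.85, t2: float = 160.0) -> float:
    """Feature similarity index combining phase congruency and gradients.

    Similarity maps of the phase-congruency fields (stabiliser ``t1``) and
    Scharr gradient magnitudes (stabiliser ``t2``, calibrated for [0, 255]
    intensities) are multiplied and averaged with the pointwise maximum
    phase congruency as weight.  Value in [0, 1]; 1 for identical inputs.
    """
    im, ref = pair.image, pair.reference
    if ref is None:
        raise MetricDomainError("FSIM requires a reference slice")
    if pair.domain is not None:
        raise MetricDomainError(
            "FSIM is computed across the entire matrix; the 'mask' evaluation "
            "domain is unavailable")
    scale = check_value_range(pair, "FSIM")
    im, ref = im * scale, ref * scale

    # Large images are pooled towards the ~256-pixel scale the constants
    # were calibrated at; 64-128 voxel MR slices pass through unchanged.
    f = max(1, int(round(min(im.shape) / 256)))
    if f > 1:
        im = ndimage.uniform_filter(im, size=f, mode="nearest")[::f, ::f]
        ref = ndimage.uniform_filter(ref, size=f, mode="nearest")[::f, ::f]

    pc1, pc2 = phase_congruency(im), phase_congruency(ref)
    g1, g2 = _scharr_magnitude(im), _scharr_magnitude(ref)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    pcm = np.maximum(pc1, pc2)
    w = float(pcm.sum())
    if w <= 0:
        raise DegenerateVolumeError("no phase-congruency support (blank slices)")
    return float((s_pc * s_g * pcm).sum() / w)


# --------------------------------------------------------------------------
# VIF (pixel-domain, multi-scale Gaussian windows)
# --------------------------------------------------------------------------

def vif(pair: SlicePair, sigma_nsq: float = 2.0) -> float:
    """Visual information fidelity, pixel-domain variant (VIFp).

    The reference is modelled as a Gaussian scale mixture and the degraded
    image as a gain-plus-additive-noise channel acting on it; VIF is the
    ratio of the information the degraded image preserves about the source
    to the information in the reference itself, summed over four dyadic
    scales.  1 for identical inputs, < 1 for information loss, and > 1 when
    the "distortion" enhances contrast.  ``sigma_nsq`` is the visual-noise
    variance in [0, 255] units.
    """
    im, ref = pair.image, pair.reference
    if ref is None:
        raise MetricDomainError("VIF requires a reference slice")
    if pair.domain is not None:
        raise MetricDomainError(
            "VIF is computed across the entire matrix; the 'mask' evaluation "
            "domain is unavailable")
    scale = check_value_range(pair, "VIF")
    dist = im * scale
    ref = ref * scale

    eps = 1e-10
    num = den = 0.0
    for s in range(1, 5):
        n = 2 ** (4 - s + 1) + 1
        sd = n / 5.0
        truncate = ((n - 1) / 2) / sd
        if s > 1:
            ref = ndimage.gaussian_filter(ref, sd, truncate=truncate,
                                          mode="nearest")[::2, ::2]
            dist = ndimage.gaussian_filter(dist, sd, truncate=truncate,
                                           mode="nearest")[::2, ::2]

        def gf(a: np.ndarray) -> np.ndarray:
            return ndimage.gaussian_filter(a, sd, truncate=truncate, mode="nearest")

        mu1, mu2 = gf(ref), gf(dist)
        s1 = np.maximum(gf(ref * ref) - mu1 * mu1, 0.0)
        s2 = np.maximum(gf(dist * dist) - mu2 * mu2, 0.0)
        s12 = gf(ref * dist) - mu1 * mu2

        valid = s1 > eps
        g = np.zeros_like(s1)
        np.divide(s12, s1, out=g, where=valid)
        sv = s2 - g * s12
        neg = g < 0
        sv[neg] = s2[neg]
        g[neg] = 0.0
        sv = np.maximum(sv, 0.0)

        num += float(np.log(1.0 + (g ** 2) * s1 / (sv + sigma_nsq))[valid].sum())
        den += float(np.log(1.0 + s1 / sigma_nsq)[valid].sum())
    if den == 0.0:
        raise DegenerateVolumeError("constant reference carries no information")
    return num / den


register(MetricSpec("SSIM", Direction.HIGHER_BETTER, True, "any", ssim))
register(MetricSpec("PSNR", Direction.HIGHER_BETTER, True, "any", psnr))
register(MetricSpec("FSIM", Direction.HIGHER_BETTER, True, "unit_or_255", fsim))
register(MetricSpec("VIF", Direction.HIGHER_BETTER, True, "unit_or_255", vif,
                    variant="VIFp"))
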