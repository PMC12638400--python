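"""Volume and brain-mask data model plus the slice-wise pre-processing grid.

A quality evaluation run touches three independent pre-processing axes:

* **masking** -- ignore the brain mask, multiply it into the image (zeroing
  the background), or restrict the metric's evaluation domain to in-mask
  voxels;
* **normalization** -- none, min-max, mean/standard-deviation, or a robust
  percentile mapping (1st percentile -> 0, 99.9th -> 1, clipped);
* **slice reduction** -- summarise the per-slice metric values by their mean
  or by the worst slice (min or max depending on the metric's quality
  direction).

Normalization is always applied volume-wise (never per slice) and is
computed on the volume as presented to the pipeline, *before* any mask
multiplication, so the four normalization modes mean the same thing in every
masking mode.  The alternative ordering is one flag away in
:func:`preprocess_volume`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MaskMode",
    "NormMode",
    "Reduction",
    "Volume",
    "BrainMask",
    "PreprocConfig",
    "SlicePair",
    "DegenerateVolumeError",
    "normalize_volume",
    "apply_mask_mode",
    "select_slices",
    "reduce_slicewise",
    "masked_histogram",
    "iter_slice_pairs",
    "preprocess_volume",
]


class MaskMode(str, enum.Enum):
    """How the brain mask enters the metric computation."""

    NONE = "none"
    MASK = "mask"          # restrict the evaluation domain to mask voxels
    MULTIPLY = "multiply"  # zero the background, evaluate everywhere


class NormMode(str, enum.Enum):
    NONE = "none"
    MINMAX = "minmax"
    MEANSTD = "meanstd"
    PERCENTILE = "percentile"


class Reduction(str, enum.Enum):
    MEAN = "mean"
    WORST = "worst"


class DegenerateVolumeError(ValueError):
    """Raised when an operation is undefined on the given intensities."""


@dataclass
class Volume:
    """A 3D magnitude image.

    Parameters
    ----------
    data:
        Non-negative 3D intensity array (arbitrary units before
        normalization).
    slice_axis:
        Index of the acquisition slice axis; per-slice metrics iterate
        along this axis.
    voxel_size:
        Voxel edge lengths in mm.
    id:
        Subject/acquisition label used in reports.
    """

    data: np.ndarray
    slice_axis: int = 2
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if min(self.data.shape) < 8:
            raise ValueError(f"every dimension must be >= 8, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if not np.any(self.data > 0):
            raise ValueError("volume must contain at least one positive voxel")
        if not -3 <= self.slice_axis < 3:
            raise ValueError(f"slice_axis {self.slice_axis} out of range for 3D data")
        self.slice_axis = int(self.slice_axis) % 3

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    def get_slice(self, index: int) -> np.ndarray:
        return np.take(self.data, index, axis=self.slice_axis)

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, slice_axis=self.slice_axis,
                      voxel_size=self.voxel_size, id=self.id)


@dataclass
class BrainMask:
    """Binary brain mask co-registered with a :class:`Volume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = arr.astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty")

    def check_paired(self, v: Volume) -> None:
        if self.data.shape != v.data.shape:
            raise ValueError(
                f"mask shape {self.data.shape} != volume shape {v.data.shape}")

    def get_slice(self, index: int, axis: int) -> np.ndarray:
        return np.take(self.data, index, axis=axis)


@dataclass(frozen=True)
class PreprocConfig:
    """One cell of the masking x normalization x reduction decision grid."""

    mask_mode: MaskMode = MaskMode.MULTIPLY
    norm_mode: NormMode = NormMode.PERCENTILE
    reduction: Reduction = Reduction.WORST
    min_brain_fraction: float = 0.1
    percentile_bounds: tuple[float, float] = (1.0, 99.9)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask_mode", MaskMode(self.mask_mode))
        object.__setattr__(self, "norm_mode", NormMode(self.norm_mode))
        object.__setattr__(self, "reduction", Reduction(self.reduction))
        lo, hi = self.percentile_bounds
        if not (0 <= lo < hi <= 100):
            raise ValueError("percentile_bounds must be strictly increasing within [0, 100]")
        if not 0 <= self.min_brain_fraction <= 1:
            raise ValueError("min_brain_fraction must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.mask_mode.value}-{self.norm_mode.value}-{self.reduction.value}"


@dataclass
class SlicePair:
    """A 2D evaluation unit: image slice, optional reference, optional domain.

    ``domain`` is the evaluation-domain mask (True where the metric is
    evaluated); ``None`` means the full rectangular grid.
    """

    image: np.ndarray
    reference: Optional[np.ndarray] = None
    domain: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise ValueError("image slice must be 2D")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=np.float64)
            if self.reference.shape != self.image.shape:
                raise ValueError("reference slice shape mismatch")
        if self.domain is not None:
            self.domain = np.asarray(self.domain, dtype=bool)
            if self.domain.shape != self.image.shape:
                raise ValueError("domain mask shape mismatch")


def normalize_volume(v: Volume, mode: NormMode | str,
                     bounds: tuple[float, float] = (1.0, 99.9)) -> Volume:
    """Normalize a volume's intensities volume-wise.

    ``minmax`` maps min -> 0 and max -> 1.  ``meanstd`` subtracts the mean
    and divides by the standard deviation.  ``percentile`` maps the lower
    percentile bound -> 0 and the upper bound -> 1 (linear-interpolation
    percentiles over the full intensity vector) and clips to [0, 1], which
    makes the result robust to a handful of extreme outlier voxels.
    """
    mode = NormMode(mode)
    if mode is NormMode.NONE:
        return v
    x = v.data
    if mode is NormMode.MINMAX:
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            raise DegenerateVolumeError("constant volume cannot be min-max normalized")
        return v.with_data((x - lo) / (hi - lo))
    if mode is NormMode.MEANSTD:
        sd = float(x.std())
        if sd == 0:
            raise DegenerateVolumeError("constant volume has zero standard deviation")
        return v.with_data((x - x.mean()) / sd)
    if mode is NormMode.PERCENTILE:
        lo, hi = np.percentile(x, bounds)
        if hi == lo:
            raise DegenerateVolumeError("degenerate percentile bounds (constant bulk)")
        return v.with_data(np.clip((x - lo) / (hi - lo), 0.0, 1.0))
    raise ValueError(mode)  # pragma: no cover


def apply_mask_mode(v: Volume, m: Optional[BrainMask],
                    mode: MaskMode | str) -> tuple[Volume, Optional[np.ndarray]]:
    """Prepare a volume for metric evaluation under a masking mode.

    Returns the (possibly background-zeroed) volume and the evaluation
    domain: ``None`` for the full grid, or a boolean array restricting the
    metric to in-mask voxels (``mask`` mode).
    """
    mode = MaskMode(mode)
    if mode is MaskMode.NONE:
        return v, None
    if m is None:
        raise ValueError(f"mask mode '{mode.value}' requires a brain mask")
    m.check_paired(v)
    if mode is MaskMode.MULTIPLY:
        return v.with_data(v.data * m.data), None
    return v, m.data.copy()


def select_slices(m: BrainMask, min_brain_fraction: float = 0.1,
                  axis: int = 2) -> list[int]:
    """Indices of slices whose in-mask voxel fraction reaches the threshold.

    Peripheral slices with little brain coverage produce unstable metric
    values; the default keeps slices with at least 10% brain voxels.  Slices
    without any brain voxel are never selected.
    """
    axis = int(axis) % 3
    other = tuple(a for a in range(3) if a != axis)
    counts = m.data.sum(axis=other)
    slice_area = np.prod([m.data.shape[a] for a in other])
    frac = counts / slice_area
    keep = (counts > 0) & (frac >= min_brain_fraction)
    return [int(i) for i in np.nonzero(keep)[0]]


def reduce_slicewise(values: Sequence[float], reduction: Reduction | str,
                     direction: str = "higher_better") -> float:
    """Reduce per-slice metric values to a single scalar.

    ``worst`` takes the most degraded slice: the minimum for higher-is-better
    metrics and the maximum for lower-is-better ones.  Missing values (NaN,
    e.g. a slice without detected edges) are excluded.
    """
    reduction = Reduction(reduction)
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined slice values to reduce")
    if reduction is Reduction.MEAN:
        return float(arr.mean())
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown quality direction {direction!r}")
    return float(arr.min() if direction == "higher_better" else arr.max())


def masked_histogram(v: Volume, m: BrainMask,
                     n_bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of in-mask intensities; a normalization diagnostic.

    Comparing the in-mask histograms of a degraded image and its reference
    under different normalizations shows which mapping aligns the two
    intensity distributions (min-max is derailed by single outlier voxels,
    the percentile mapping is not).

    Returns ``(bin_edges, counts)``; counts sum to the in-mask voxel count.
    """
    m.check_paired(v)
    vals = v.data[m.data]
    if vals.size == 0:
        raise ValueError("empty mask")
    counts, edges = np.histogram(vals, bins=n_bins)
    return edges, counts


def preprocess_volume(v: Volume, m: Optional[BrainMask], cfg: PreprocConfig,
                      mask_before_norm: bool = False,
                      ) -> tuple[Volume, Optional[np.ndarray], list[int]]:
    """Run one grid cell's normalization + masking + slice selection.

    Returns the prepared volume, the evaluation-domain array (or ``None``)
    and the selected slice indices.  By default normalization statistics are
    computed before mask multiplication; set ``mask_before_norm`` for the
    alternative ordering.
    """
    if m is not None:
        m.check_paired(v)
        indices = select_slices(m, cfg.min_brain_fraction, axis=v.slice_axis)
    else:
        if cfg.mask_mode is not MaskMode.NONE:
            raise ValueError(f"mask mode '{cfg.mask_mode.value}' requires a mask")
        indices = list(range(v.n_slices))
    if mask_before_norm:
        v, domain = apply_mask_mode(v, m, cfg.mask_mode)
        v = normalize_volume(v, cfg.norm_mode, cfg.percentile_bounds)
    else:
        v = normalize_volume(v, cfg.norm_mode, cfg.percentile_bounds)
        v, domain = apply_mask_mode(v, m, cfg.mask_mode)
    return v, domain, indices


def iter_slice_pairs(image: Volume, reference: Optional[Volume],
                     domain: Optional[np.ndarray],
                     indices: Sequence[int]):
    """Yield ``(slice_index, SlicePair)`` for the selected slices."""
    axis = image.slice_axis
    for idx in indices:
        yield idx, SlicePair(
            image=image.get_slice(idx),
            reference=None if reference is None else reference.get_slice(idx),
            domain=None if domain is None else np.take(domain, idx, axis=axis),
        )
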