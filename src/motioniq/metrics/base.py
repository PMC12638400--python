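"""Metric registry.

Every metric is registered with a :class:`MetricSpec` describing its quality
direction (used to pick the worst slice), whether it needs a reference, and
the input range it requires.  Third-party metrics (e.g. learned perceptual
distances such as LPIPS, which need pretrained network weights that this
package does not ship) can be plugged in with :func:`register`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np

from ..volume import PreprocConfig, SlicePair

__all__ = [
    "Direction",
    "MetricSpec",
    "MetricValue",
    "MetricDomainError",
    "register",
    "get_metric",
    "metric_names",
    "compute_metric",
    "REFERENCE_BASED",
    "REFERENCE_FREE",
]


class Direction(str, enum.Enum):
    """Whether larger values mean better perceived quality."""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class MetricDomainError(ValueError):
    """Metric cannot be evaluated under the requested domain/range."""


@dataclass(frozen=True)
class MetricSpec:
    name: str
    direction: Direction
    requires_reference: bool
    required_range: str = "any"      # "any" or "unit_or_255"
    func: Optional[Callable[..., float]] = None
    variant: str = ""                # implementation variant, e.g. "VIFp"

    def __call__(self, pair: SlicePair, **kwargs) -> float:
        if self.func is None:
            raise NotImplementedError(
                f"metric {self.name!r} is a registry slot without an implementation")
        if self.requires_reference and pair.reference is None:
            raise MetricDomainError(f"{self.name} requires a reference slice")
        return self.func(pair, **kwargs)


@dataclass
class MetricValue:
    """Per-slice values and their reduced scalar for one (volume, metric, cell)."""

    metric: MetricSpec
    per_slice: Dict[int, float]
    reduced: float
    preproc: PreprocConfig

    def __post_init__(self) -> None:
        if not self.per_slice:
            raise ValueError("per_slice must be non-empty")


_REGISTRY: Dict[str, MetricSpec] = {}

REFERENCE_BASED = ("SSIM", "PSNR", "FSIM", "VIF")
REFERENCE_FREE = ("TG", "AES", "NGS", "IE", "GE")


def register(spec: MetricSpec, overwrite: bool = False) -> MetricSpec:
    if spec.name in _REGISTRY and not overwrite:
        raise ValueError(f"metric {spec.name!r} already registered")
    _REGISTRY[spec.name] = spec
    return spec


def get_metric(name: str) -> MetricSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown metric {name!r}; available: {sorted(_REGISTRY)}") from None


def metric_names() -> list[str]:
    return [n for n in (*REFERENCE_BASED, *REFERENCE_FREE) if n in _REGISTRY] + \
        sorted(n for n in _REGISTRY if n not in REFERENCE_BASED + REFERENCE_FREE)


def compute_metric(name: str, pair: SlicePair, **kwargs) -> float:
    return get_metric(name)(pair, **kwargs)


def check_value_range(pair: SlicePair, name: str) -> float:
    """Validate the [0,1]-or-[0,255] input contract; return the scale factor.

    Metrics calibrated for 8-bit natural images keep their published
    constants meaningful by mapping unit-range data onto [0, 255].
    """
    arrays = [pair.image] if pair.reference is None else [pair.image, pair.reference]
    hi = max(float(a.max()) for a in arrays)
    lo = min(float(a.min()) for a in arrays)
    if lo < -1e-9 or hi > 255 * (1 + 1e-9):
        raise MetricDomainError(
            f"{name} requires intensities in [0, 1] or [0, 255]; "
            f"observed range [{lo:.4g}, {hi:.4g}]")
    return 255.0 if hi <= 1.0 + 1e-9 else 1.0
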