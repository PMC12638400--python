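"""Grid evaluation pipeline: metrics x pre-processing cells x agreement.

For every cell of the pre-processing grid and every registered metric, each
volume is normalised, masked and sliced, the metric evaluated per selected
slice, reduced to one scalar, and the reduced values correlated with the
weighted observer scores per sequence.  Metric/cell combinations a metric
rejects (FSIM/VIF under the ``mask`` evaluation domain or under ``none`` /
``meanstd`` normalization, which violate their required input range) are
skipped and recorded with a machine-readable reason.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .agreement import (AgreementReport, RatingTable, krippendorff_alpha,
                        spearman, weighted_mean_score)
from .metrics import MetricDomainError, get_metric, metric_names
from .synthetic import SyntheticStudy
from .volume import (BrainMask, MaskMode, NormMode, PreprocConfig, Volume,
                     iter_slice_pairs, preprocess_volume, reduce_slicewise)

logger = logging.getLogger(__name__)

__all__ = [
    "EvalItem",
    "RunConfig",
    "ResultsBundle",
    "STANDARD_CELL",
    "dataset_from_study",
    "evaluate_dataset",
    "correlate",
    "run_grid",
    "compare_preproc_axes",
]

#: The reference pre-processing cell: multiply the brain mask into the
#: image, percentile-normalise, keep the worst slice.
STANDARD_CELL = PreprocConfig(mask_mode=MaskMode.MULTIPLY,
                              norm_mode=NormMode.PERCENTILE,
                              reduction="worst")

# Cells FSIM/VIF cannot evaluate, and why.
_RANGE_LIMITED = ("FSIM", "VIF")


@dataclass
class EvalItem:
    """One volume of a dataset, with its reference, mask and metadata."""

    volume: Volume
    reference: Optional[Volume]
    mask: Optional[BrainMask]
    subject: str
    sequence: str
    is_reference: bool = False
    severity: float = float("nan")

    @property
    def volume_id(self) -> str:
        return self.volume.id


@dataclass
class RunConfig:
    """What to evaluate: metrics, grid cells, seed, output location."""

    metrics: Sequence[str] = ()
    cells: Sequence[PreprocConfig] = (STANDARD_CELL,)
    include_references: bool = False
    seed: int = 0
    alpha_level_of_measurement: str = "ordinal"

    def __post_init__(self) -> None:
        if not self.metrics:
            self.metrics = tuple(metric_names())
        labels = [c.label for c in self.cells]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate pre-processing cells")


@dataclass
class ResultsBundle:
    """Everything one grid run produces."""

    per_slice: pd.DataFrame       # volume_id, sequence, cell, metric, slice_index, value
    reduced: pd.DataFrame         # volume_id, subject, sequence, cell, metric, value, ...
    agreement: Dict[str, AgreementReport]
    exclusions: pd.DataFrame      # metric, cell, reason
    provenance: dict

    def cell_report(self, cell: PreprocConfig | str) -> AgreementReport:
        label = cell if isinstance(cell, str) else cell.label
        return self.agreement[label]


def dataset_from_study(study: SyntheticStudy) -> list[EvalItem]:
    items: list[EvalItem] = []
    for sub in study.subjects:
        items.append(EvalItem(sub.reference, sub.reference, sub.mask,
                              sub.subject_id, study.sequence,
                              is_reference=True,
                              severity=sub.reference_severity))
        for vol, sev in zip(sub.degraded, sub.severities):
            items.append(EvalItem(vol, sub.reference, sub.mask,
                                  sub.subject_id, study.sequence,
                                  is_reference=False, severity=sev))
    return items


def _cell_exclusion_reason(metric: str, cell: PreprocConfig) -> Optional[str]:
    if metric not in _RANGE_LIMITED:
        return None
    if cell.mask_mode is MaskMode.MASK:
        return "requires the full rectangular grid; 'mask' evaluation domain unavailable"
    if cell.norm_mode in (NormMode.NONE, NormMode.MEANSTD):
        return (f"requires intensities in [0,1] or [0,255]; normalization "
                f"'{cell.norm_mode.value}' does not guarantee that range")
    return None


def evaluate_item(item: EvalItem, cell: PreprocConfig,
                  metrics: Sequence[str]) -> tuple[list[dict], list[dict]]:
    """Per-slice and reduced metric rows for one volume under one cell."""
    vol, domain, indices = preprocess_volume(item.volume, item.mask, cell)
    if not indices:
        raise ValueError(f"no evaluable slices for volume {item.volume_id!r}")
    ref = None
    if item.reference is not None:
        ref, _, _ = preprocess_volume(item.reference, item.mask, cell)

    per_slice_rows, reduced_rows = [], []
    values: Dict[str, list[float]] = {m: [] for m in metrics}
    for idx, pair in iter_slice_pairs(vol, ref, domain, indices):
        for name in metrics:
            spec = get_metric(name)
            if spec.requires_reference and ref is None:
                continue
            try:
                val = spec(pair)
            except (MetricDomainError, ValueError) as exc:
                logger.debug("metric %s failed on %s slice %d: %s",
                             name, item.volume_id, idx, exc)
                val = float("nan")
            values[name].append(val)
            per_slice_rows.append({
                "volume_id": item.volume_id, "subject": item.subject,
                "sequence": item.sequence, "cell": cell.label, "metric": name,
                # slice indices are 0-based internally, 1-based in reports
                "slice_index": idx + 1, "value": val,
            })
    for name in metrics:
        spec = get_metric(name)
        if spec.requires_reference and ref is None:
            continue
        vals = np.asarray(values[name], dtype=float)
        defined = vals[~np.isnan(vals)]
        reduced = (float("nan") if defined.size == 0
                   else reduce_slicewise(defined, cell.reduction,
                                         spec.direction.value))
        reduced_rows.append({
            "volume_id": item.volume_id, "subject": item.subject,
            "sequence": item.sequence, "cell": cell.label, "metric": name,
            "value": reduced, "n_slices": int(defined.size),
            "is_reference": item.is_reference, "severity": item.severity,
        })
    return per_slice_rows, reduced_rows


def evaluate_dataset(items: Sequence[EvalItem], config: RunConfig,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Metric values for every (volume, metric, cell); plus exclusions."""
    per_slice_rows: list[dict] = []
    reduced_rows: list[dict] = []
    exclusions: list[dict] = []
    for cell in config.cells:
        t0 = time.perf_counter()
        cell_metrics = []
        for name in config.metrics:
            reason = _cell_exclusion_reason(name, cell)
            if reason is not None:
                exclusions.append({"metric": name, "cell": cell.label,
                                   "reason": reason})
            else:
                cell_metrics.append(name)
        for item in items:
            if item.is_reference and not config.include_references:
                continue
            ps, rd = evaluate_item(item, cell, cell_metrics)
            per_slice_rows.extend(ps)
            reduced_rows.extend(rd)
        logger.info("cell %s: %d volumes in %.1f s", cell.label,
                    sum(1 for i in items
                        if config.include_references or not i.is_reference),
                    time.perf_counter() - t0)
    return (pd.DataFrame(per_slice_rows), pd.DataFrame(reduced_rows),
            pd.DataFrame(exclusions, columns=["metric", "cell", "reason"]))


def correlate(reduced: pd.DataFrame, ratings: RatingTable,
              config: RunConfig) -> Dict[str, AgreementReport]:
    """Agreement layer: per-cell Spearman matrices, alpha, median ranks.

    Reference volumes and volumes whose metric is undefined (NaN/inf, e.g.
    +inf PSNR) are dropped pairwise from the correlation; the number of
    volumes actually used is recorded per cell.
    """
    scores = weighted_mean_score(ratings)
    sequences = sorted(reduced["sequence"].unique())
    alpha = {}
    for seq in sequences:
        ids = reduced.loc[reduced["sequence"] == seq, "volume_id"].unique()
        sub = ratings.scores.loc[[i for i in ids if i in ratings.scores.index]]
        alpha[seq] = krippendorff_alpha(sub.to_numpy(),
                                        level=config.alpha_level_of_measurement)
    alpha = pd.Series(alpha, name="alpha")

    reports = {}
    body = reduced[~reduced["is_reference"]]
    for cell, cell_df in body.groupby("cell", sort=False):
        metrics = [m for m in config.metrics if m in set(cell_df["metric"])]
        rho = pd.DataFrame(index=metrics, columns=sequences, dtype=float)
        pval = pd.DataFrame(index=metrics, columns=sequences, dtype=float)
        nmat = pd.DataFrame(index=metrics, columns=sequences, dtype=float)
        for (metric, seq), grp in cell_df.groupby(["metric", "sequence"]):
            merged = grp.set_index("volume_id")["value"]
            y = scores.reindex(merged.index)
            ok = np.isfinite(merged.to_numpy()) & np.isfinite(y.to_numpy())
            n_drop = int((~ok).sum())
            if n_drop:
                logger.info("cell %s metric %s (%s): dropped %d volumes with "
                            "undefined values", cell, metric, seq, n_drop)
            nmat.loc[metric, seq] = int(ok.sum())
            if ok.sum() < 3:
                continue
            r, p = spearman(merged.to_numpy()[ok], y.to_numpy()[ok],
                            seed=config.seed or 20250610)
            rho.loc[metric, seq] = r
            pval.loc[metric, seq] = p
        reports[cell] = AgreementReport(
            rho=rho, p=pval, alpha=alpha.copy(), n=nmat,
            alpha_level_of_measurement=config.alpha_level_of_measurement)
    return reports


def run_grid(items: Sequence[EvalItem] | SyntheticStudy, config: RunConfig,
             ratings: Optional[RatingTable] = None) -> ResultsBundle:
    """Evaluate the full grid and correlate with observer scores."""
    if isinstance(items, SyntheticStudy):
        if ratings is None:
            ratings = items.ratings
        items = dataset_from_study(items)
    if ratings is None:
        raise ValueError("ratings are required to correlate with observer scores")
    missing = {i.volume_id for i in items if not i.is_reference} \
        - set(ratings.scores.index)
    if missing:
        raise ValueError(f"ratings missing for volumes: {sorted(missing)[:5]} ...")
    per_slice, reduced, exclusions = evaluate_dataset(items, config)
    agreement = correlate(reduced, ratings, config)
    provenance = {
        "software": f"motioniq {_version}",
        "seed": config.seed,
        "metrics": list(config.metrics),
        "cells": [c.label for c in config.cells],
        "alpha_level_of_measurement": config.alpha_level_of_measurement,
        "n_volumes": int(reduced["volume_id"].nunique()) if len(reduced) else 0,
    }
    return ResultsBundle(per_slice=per_slice, reduced=reduced,
                         agreement=agreement, exclusions=exclusions,
                         provenance=provenance)


def axis_variant_cells(standard: PreprocConfig = STANDARD_CELL,
                       ) -> list[PreprocConfig]:
    """The standard cell plus every single-axis variant of it."""
    cells = [standard]
    for mm in MaskMode:
        if mm is not standard.mask_mode:
            cells.append(PreprocConfig(mm, standard.norm_mode, standard.reduction))
    for nm in NormMode:
        if nm is not standard.norm_mode:
            cells.append(PreprocConfig(standard.mask_mode, nm, standard.reduction))
    for rd in ("mean", "worst"):
        if rd != standard.reduction.value:
            cells.append(PreprocConfig(standard.mask_mode, standard.norm_mode, rd))
    return cells


def compare_preproc_axes(bundle: ResultsBundle,
                         standard: PreprocConfig = STANDARD_CELL,
                         sequence: Optional[str] = None) -> pd.DataFrame:
    """Per-axis comparison table of rho, one axis varied at a time.

    Rows are metrics; columns are (axis, option) pairs, with the standard
    cell's option duplicated in every axis as the baseline.  Cells a metric
    cannot evaluate are NaN.
    """
    if standard.label not in bundle.agreement:
        raise ValueError("bundle does not contain the standard cell")

    def cell_rho(cell: PreprocConfig) -> Optional[pd.Series]:
        rep = bundle.agreement.get(cell.label)
        if rep is None:
            return None
        rho = rep.rho
        col = sequence or rho.columns[0]
        return rho[col]

    columns = {}
    for axis, options, make in (
        ("mask", [m.value for m in MaskMode],
         lambda o: PreprocConfig(o, standard.norm_mode, standard.reduction)),
        ("normalization", [n.value for n in NormMode],
         lambda o: PreprocConfig(standard.mask_mode, o, standard.reduction)),
        ("reduction", ["mean", "worst"],
         lambda o: PreprocConfig(standard.mask_mode, standard.norm_mode, o)),
    ):
        for opt in options:
            series = cell_rho(make(opt))
            if series is not None:
                columns[(axis, opt)] = series
    out = pd.DataFrame(columns)
    out = out.reindex(bundle.agreement[standard.label].rho.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["axis", "option"])
    return out
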