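"""NIfTI and tabular input/output.

A dataset on disk is described by a manifest CSV with columns
``subject_id, sequence, condition, volume_path, mask_path, is_reference``
(paths relative to the manifest), plus a tidy ratings CSV with columns
``volume_id, rater_id, role, score``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .agreement import RatingTable
from .pipeline import EvalItem
from .synthetic import SyntheticStudy
from .volume import BrainMask, Volume

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "write_study",
    "load_manifest",
    "load_ratings",
]

MANIFEST_COLUMNS = ["subject_id", "sequence", "condition", "volume_path",
                    "mask_path", "is_reference"]


def _slice_axis_from_header(img: nib.Nifti1Image) -> int:
    """The acquisition slice axis from dim_info when set, else the last axis."""
    _, _, slice_dim = img.header.get_dim_info()
    return slice_dim if slice_dim is not None else img.ndim - 1


def load_volume(path: str | os.PathLike, volume_id: Optional[str] = None) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    vid = volume_id if volume_id is not None else Path(path).name.split(".nii")[0]
    return Volume(data=data, slice_axis=_slice_axis_from_header(img),
                  voxel_size=voxel, id=vid)


def save_volume(v: Volume, path: str | os.PathLike) -> None:
    affine = np.diag((*v.voxel_size, 1.0))
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    img.header.set_dim_info(slice=v.slice_axis)
    img.header.set_zooms(v.voxel_size)
    nib.save(img, str(path))


def load_mask(path: str | os.PathLike) -> BrainMask:
    img = nib.load(str(path))
    return BrainMask(data=(np.asanyarray(img.dataobj) > 0.5).astype(np.uint8))


def save_mask(m: BrainMask, path: str | os.PathLike,
              voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(m.data.astype(np.uint8), np.diag((*voxel_size, 1.0)))
    nib.save(img, str(path))


def write_study(study: SyntheticStudy, outdir: str | os.PathLike) -> Path:
    """Write a synthetic study as NIfTI volumes + manifest + ratings CSVs.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sub in study.subjects:
        mask_path = f"{sub.subject_id}_mask.nii.gz"
        save_mask(sub.mask, outdir / mask_path, sub.reference.voxel_size)
        for vol, sev, is_ref, cond in (
                [(sub.reference, 0.0, True, 0)]
                + [(v, s, False, k) for k, (v, s)
                   in enumerate(zip(sub.degraded, sub.severities), 1)]):
            vol_path = f"{vol.id}.nii.gz"
            save_volume(vol, outdir / vol_path)
            rows.append({"subject_id": sub.subject_id, "sequence": study.sequence,
                         "condition": cond, "volume_path": vol_path,
                         "mask_path": mask_path, "is_reference": is_ref,
                         "severity": sev})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    study.ratings.to_tidy().to_csv(outdir / "ratings.csv", index=False)
    return manifest


def load_manifest(path: str | os.PathLike) -> list[EvalItem]:
    """Load a manifest CSV into evaluation items (volumes read eagerly)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = path.parent
    items: list[EvalItem] = []
    for (subject, sequence), grp in df.groupby(["subject_id", "sequence"]):
        refs = grp[grp["is_reference"].astype(bool)]
        reference = (load_volume(base / refs.iloc[0]["volume_path"])
                     if len(refs) else None)
        for _, row in grp.iterrows():
            mask = (load_mask(base / row["mask_path"])
                    if isinstance(row["mask_path"], str) and row["mask_path"]
                    else None)
            is_ref = bool(row["is_reference"])
            vol = reference if is_ref and reference is not None \
                else load_volume(base / row["volume_path"])
            items.append(EvalItem(
                volume=vol, reference=reference, mask=mask,
                subject=str(subject), sequence=str(sequence),
                is_reference=is_ref,
                severity=float(row.get("severity", float("nan")))))
    return items


def load_ratings(path: str | os.PathLike) -> RatingTable:
    return RatingTable.from_tidy(pd.read_csv(path))
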