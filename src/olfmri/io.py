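"""Readers and writers for the on-disk exchange formats.

NIfTI volumes go through nibabel; tabular artifacts are TSV; motion traces
use the 6-column whitespace-delimited realignment-parameter dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Cohort
from .mvpa import GreyMatterMap
from .prep import ROIAtlas, ROITimeSeriesMatrix

__all__ = [
    "save_cohort",
    "load_gm_maps",
    "load_atlas",
    "load_timeseries",
    "load_motion",
    "load_subjects",
    "save_timeseries",
]


def _nifti(values: np.ndarray, affine: np.ndarray, dtype) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(values, dtype=dtype), affine)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write every cohort artifact under ``out_dir``.

    Layout: gm/sub-*_gm.nii.gz + gm/mask.nii.gz, atlas.nii.gz + labels.tsv,
    ts/sub-*_ts.tsv (rows = volumes, columns = ROI labels),
    motion/sub-*_motion.txt, subjects.tsv, ground_truth.json.
    """
    out = Path(out_dir)
    (out / "gm").mkdir(parents=True, exist_ok=True)
    (out / "ts").mkdir(exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    cfg = cohort.config
    affine = cfg.affine()

    mask = cohort.subjects[0].gm_map.brain_mask
    _nifti(mask, affine, np.uint8).to_filename(out / "gm" / "mask.nii.gz")
    for s in cohort.subjects:
        _nifti(s.gm_map.values, affine, np.float32).to_filename(
            out / "gm" / f"{s.subject_id}_gm.nii.gz"
        )
        ts = pd.DataFrame(
            s.roi_ts.data.T, columns=[str(l) for l in s.roi_ts.roi_labels]
        )
        ts.to_csv(out / "ts" / f"{s.subject_id}_ts.tsv", sep="\t", index=False)
        np.savetxt(out / "motion" / f"{s.subject_id}_motion.txt", s.motion, fmt="%.8f")

    _nifti(cohort.atlas.labels, affine, np.int16).to_filename(out / "atlas.nii.gz")
    cohort.atlas.meta.to_csv(out / "labels.tsv", sep="\t", index=False)

    rows = []
    for s in cohort.subjects:
        o = s.olfactory
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "T": o.threshold if o else np.nan,
                "D": o.discrimination if o else np.nan,
                "I": o.identification if o else np.nan,
                "TDI": o.tdi if o else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)

    truth = {
        "planted_clusters": [
            {
                "center_voxel": list(c.center_voxel),
                "radius_vox": c.radius_vox,
                "effect_style": c.effect_style,
                "effect_size": c.effect_size,
            }
            for c in cfg.planted_clusters
        ],
        "coupling_bursts": cohort.coupling_truth,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def load_subjects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_gm_maps(
    gm_dir: str | Path, subject_ids, voxel_size_mm: float | None = None
) -> tuple[list[GreyMatterMap], np.ndarray]:
    gm_dir = Path(gm_dir)
    mask_img = nib.load(gm_dir / "mask.nii.gz")
    mask = np.asarray(mask_img.dataobj).astype(bool)
    vox = voxel_size_mm or float(mask_img.header.get_zooms()[0])
    maps = []
    for sid in subject_ids:
        img = nib.load(gm_dir / f"{sid}_gm.nii.gz")
        maps.append(
            GreyMatterMap(
                values=np.asarray(img.dataobj, dtype=float),
                voxel_size_mm=vox,
                affine=img.affine,
                brain_mask=mask,
            )
        )
    return maps, maps[0].affine


def load_atlas(atlas_path: str | Path, labels_path: str | Path) -> ROIAtlas:
    img = nib.load(atlas_path)
    meta = pd.read_csv(labels_path, sep="\t")
    return ROIAtlas(
        labels=np.asarray(img.dataobj).astype(int), meta=meta, affine=img.affine
    )


def load_timeseries(ts_dir: str | Path, subject_ids) -> list[ROITimeSeriesMatrix]:
    ts_dir = Path(ts_dir)
    out = []
    for sid in subject_ids:
        df = pd.read_csv(ts_dir / f"{sid}_ts.tsv", sep="\t")
        out.append(
            ROITimeSeriesMatrix(
                data=df.to_numpy(dtype=float).T,
                roi_labels=np.array([int(c) for c in df.columns]),
                subject_id=sid,
            )
        )
    return out


def save_timeseries(ts_list, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in ts_list:
        pd.DataFrame(ts.data.T, columns=[str(l) for l in ts.roi_labels]).to_csv(
            out / f"{ts.subject_id}_ts.tsv", sep="\t", index=False
        )


def load_motion(motion_dir: str | Path, subject_ids) -> list[np.ndarray]:
    motion_dir = Path(motion_dir)
    return [np.loadtxt(motion_dir / f"{sid}_motion.txt") for sid in subject_ids]
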