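"""On-disk artifacts: NIfTI-1 volumes and maps, BIDS-style events TSV,
JSON manifests / ground truth, and TSV report tables.

All computation elsewhere happens in voxel space; the NIfTI affine is
carried through untouched. TR is stored in the NIfTI time-step header
field (fourth zoom).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .synthio import DesignSpec, GroundTruth, Volume4D


@dataclass
class BrainMask:
    """Binary 3D analysis mask; the in-mask voxel count is the 'whole brain'
    denominator for all volume percentages."""

    values: np.ndarray
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("BrainMask requires a 3D array")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("BrainMask values must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        if self.values.sum() == 0:
            raise ValueError("BrainMask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def grid_dims(self):
        return self.values.shape


@dataclass
class CohortManifest:
    """Paths and shared acquisition parameters for one simulated cohort."""

    subject_ids: list
    run_paths: dict      # subject id -> list of run file paths
    events_path: str
    tr: float
    mask_path: str = None
    ground_truth_path: str = None

    def to_jsonable(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "run_paths": {k: list(v) for k, v in self.run_paths.items()},
            "events_path": self.events_path,
            "tr": self.tr,
            "mask_path": self.mask_path,
            "ground_truth_path": self.ground_truth_path,
        }


def write_volume4d(v: Volume4D, path: str) -> None:
    img = nib.Nifti1Image(v.data.astype(np.float32), v.affine)
    img.header.set_zooms(tuple(v.voxel_size_mm) + (float(v.tr),))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)


def read_volume4d(path: str) -> Volume4D:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: volume contains non-finite voxels")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    return Volume4D(
        data, voxel_size_mm=tuple(float(z) for z in zooms[:3]), tr=tr,
        affine=np.asarray(img.affine),
    )


def write_volume3d(values: np.ndarray, path: str, voxel_size_mm=(3.0, 3.0, 3.0),
                   affine=None, dtype=np.float32) -> None:
    """Write a 3D map/mask (t-map, overlap map, sub-network mask) as NIfTI-1."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D array, got {values.ndim}D")
    if affine is None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(values.astype(dtype), affine)
    img.header.set_zooms(tuple(voxel_size_mm))
    nib.save(img, path)


def read_volume3d(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    return data


def write_mask(mask: BrainMask, path: str) -> None:
    write_volume3d(mask.values, path, mask.voxel_size_mm, dtype=np.uint8)


def read_mask(path: str, expect_grid=None) -> BrainMask:
    values = read_volume3d(path)
    mask = BrainMask(values.astype(np.uint8))
    if expect_grid is not None and mask.grid_dims != tuple(expect_grid):
        raise ValueError(
            f"{path}: mask grid {mask.grid_dims} does not match cohort grid "
            f"{tuple(expect_grid)}"
        )
    return mask


def write_events(design: DesignSpec, path: str) -> None:
    rows = [
        {"onset": onset, "duration": duration, "condition": cond}
        for cond in design.conditions
        for onset, duration in design.events.get(cond, [])
    ]
    df = pd.DataFrame(rows, columns=["onset", "duration", "condition"])
    df = df.sort_values("onset") if len(df) else df
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str, tr: float, n_timepoints: int) -> DesignSpec:
    """Load a tab-separated events file (columns onset/duration/condition)
    and validate the timing against the run length."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such events file: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: events file needs columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"{path}: events file has no events")
    conditions = list(pd.unique(df["condition"]))
    events = {
        c: [(float(r.onset), float(r.duration))
            for r in df[df["condition"] == c].itertuples()]
        for c in conditions
    }
    return DesignSpec(conditions, events, tr, n_timepoints)  # validates timing


def write_table(rows, path: str, columns=None, float_fmt: str = "%.4f") -> None:
    """Tab-separated report table; header always present, fixed precision."""
    df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh)


def read_ground_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_jsonable(json.load(fh))


def write_cohort(volumes, design: DesignSpec, out_dir: str,
                 truth: GroundTruth = None, mask: BrainMask = None) -> CohortManifest:
    """Persist a simulated cohort: one .nii.gz per subject-run, the events
    TSV, optional ground truth JSON and mask, plus a manifest JSON."""
    os.makedirs(out_dir, exist_ok=True)
    subject_ids, run_paths = [], {}
    for i, v in enumerate(volumes):
        sid = f"sub-{i + 1:02d}"
        p = os.path.join(out_dir, f"{sid}_bold.nii.gz")
        write_volume4d(v, p)
        subject_ids.append(sid)
        run_paths[sid] = [p]
    events_path = os.path.join(out_dir, "events.tsv")
    write_events(design, events_path)
    gt_path = mask_path = None
    if truth is not None:
        gt_path = os.path.join(out_dir, "ground_truth.json")
        write_ground_truth(truth, gt_path)
    if mask is not None:
        mask_path = os.path.join(out_dir, "mask.nii.gz")
        write_mask(mask, mask_path)
    manifest = CohortManifest(subject_ids, run_paths, events_path,
                              tr=volumes[0].tr, mask_path=mask_path,
                              ground_truth_path=gt_path)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest.to_jsonable(), fh, indent=2)
    return manifest


def read_manifest(path: str) -> CohortManifest:
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such manifest: {path}")
    with open(path) as fh:
        d = json.load(fh)
    m = CohortManifest(
        subject_ids=d["subject_ids"], run_paths=d["run_paths"],
        events_path=d["events_path"], tr=d["tr"],
        mask_path=d.get("mask_path"), ground_truth_path=d.get("ground_truth_path"),
    )
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p):
        return p if p is None or os.path.isabs(p) else os.path.join(base, p)

    m.run_paths = {k: [resolve(p) for p in v] for k, v in m.run_paths.items()}
    m.events_path = resolve(m.events_path)
    m.mask_path = resolve(m.mask_path)
    m.ground_truth_path = resolve(m.ground_truth_path)
    for sid in m.subject_ids:
        for p in m.run_paths[sid]:
            if not os.path.exists(p):
                raise FileNotFoundError(f"manifest run missing: {p}")
    return m
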