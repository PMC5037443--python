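"""Reading and writing the package's on-disk formats.

MESE stacks and label volumes travel as NIfTI (via nibabel): either one 4D
file (echo along the 4th axis) or one 3D file per echo, with a JSON sidecar
holding echo times, TR and spacing.  Segmentations are an integer plate
label volume plus a boundary label volume (1 = bone interface, 2 = surface)
and a sidecar with the plate code map and landmarks.  Cohorts and laminar
summaries are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitting import MESESeries, T2Map
from .laminar import CartilageSegmentation, LaminarSummary
from .synthetic import GroundTruth

BONE_CODE, SURFACE_CODE = 1, 2

COHORT_COLUMNS = [
    "subject_id", "group", "age", "sex", "bmi", "visit", "plate", "layer", "t2_ms",
]


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _save_nifti(data: np.ndarray, spacing: Sequence[float], path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing))
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# MESE series
# --------------------------------------------------------------------------

def save_mese(series: MESESeries, out_dir: str | Path, stem: str = "mese", per_echo: bool = False) -> Path:
    """Write a MESE series (4D NIfTI by default) plus JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if per_echo:
        for i in range(series.n_echoes):
            _save_nifti(series.volumes[i], series.voxel_spacing_mm, out_dir / f"{stem}_echo{i + 1}.nii")
    else:
        # echo as the 4th axis; spatial axes first as NIfTI expects
        data = np.moveaxis(series.volumes, 0, -1)
        _save_nifti(data, series.voxel_spacing_mm, out_dir / f"{stem}.nii")
    sidecar = {
        "echo_times_ms": list(series.echo_times_ms),
        "tr_ms": series.tr_ms,
        "voxel_spacing_mm": list(series.voxel_spacing_mm),
        "per_echo": per_echo,
        "n_echoes": series.n_echoes,
    }
    side = out_dir / f"{stem}.json"
    side.write_text(json.dumps(sidecar, indent=2))
    return side


def load_mese(sidecar: str | Path) -> MESESeries:
    """Load a MESE series from its JSON sidecar (4D or per-echo layout)."""
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    stem = sidecar.stem
    if meta.get("per_echo"):
        vols = []
        for i in range(meta["n_echoes"]):
            p = sidecar.parent / f"{stem}_echo{i + 1}.nii"
            vols.append(np.asarray(nib.load(str(p)).dataobj, dtype=float))
        shapes = {v.shape for v in vols}
        if len(shapes) > 1:
            raise ValidationError(f"echo volumes have mismatched shapes: {sorted(shapes)}")
        volumes = np.stack(vols)
    else:
        data = np.asarray(nib.load(str(sidecar.parent / f"{stem}.nii")).dataobj, dtype=float)
        volumes = np.moveaxis(data, -1, 0)
    return MESESeries(
        volumes=volumes,
        echo_times_ms=tuple(meta["echo_times_ms"]),
        tr_ms=float(meta["tr_ms"]),
        voxel_spacing_mm=tuple(meta["voxel_spacing_mm"]),
    )


# --------------------------------------------------------------------------
# Segmentation / ground truth / T2 maps
# --------------------------------------------------------------------------

def save_segmentation(seg: CartilageSegmentation, out_dir: str | Path, stem: str = "seg") -> Path:
    """Write plate labels, boundary labels and a sidecar with the code map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plates = sorted(seg.plate_masks)
    labels = np.zeros(seg.shape, dtype=float)
    codes = {}
    for i, name in enumerate(plates, start=1):
        labels[seg.plate_masks[name]] = i
        codes[name] = i
    boundary = np.zeros(seg.shape, dtype=float)
    boundary[seg.bone_interface] = BONE_CODE
    boundary[seg.surface] = SURFACE_CODE
    _save_nifti(labels, seg.voxel_spacing_mm, out_dir / f"{stem}_plates.nii")
    _save_nifti(boundary, seg.voxel_spacing_mm, out_dir / f"{stem}_boundaries.nii")
    sidecar = {
        "plate_codes": codes,
        "boundary_codes": {"bone_interface": BONE_CODE, "surface": SURFACE_CODE},
        "voxel_spacing_mm": list(seg.voxel_spacing_mm),
        "landmarks": dict(seg.landmarks),
    }
    side = out_dir / f"{stem}.json"
    side.write_text(json.dumps(sidecar, indent=2))
    return side


def load_segmentation(sidecar: str | Path) -> CartilageSegmentation:
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    stem = sidecar.stem
    labels = np.asarray(nib.load(str(sidecar.parent / f"{stem}_plates.nii")).dataobj)
    boundary = np.asarray(nib.load(str(sidecar.parent / f"{stem}_boundaries.nii")).dataobj)
    masks = {name: labels == code for name, code in meta["plate_codes"].items()}
    return CartilageSegmentation(
        plate_masks=masks,
        bone_interface=boundary == meta["boundary_codes"]["bone_interface"],
        surface=boundary == meta["boundary_codes"]["surface"],
        voxel_spacing_mm=tuple(meta["voxel_spacing_mm"]),
        landmarks={k: int(v) for k, v in meta.get("landmarks", {}).items()},
    )


def save_ground_truth(truth: GroundTruth, spacing: Sequence[float], out_dir: str | Path, stem: str = "truth") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _save_nifti(truth.true_t2_ms, spacing, out_dir / f"{stem}_t2.nii")
    _save_nifti(truth.true_depth, spacing, out_dir / f"{stem}_depth.nii")
    _save_nifti(truth.true_layer.astype(float), spacing, out_dir / f"{stem}_layer.nii")


def save_t2_map(t2map: T2Map, spacing: Sequence[float], out_dir: str | Path, stem: str = "t2map") -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _save_nifti(t2map.t2_ms, spacing, out_dir / f"{stem}_t2.nii")
    _save_nifti(t2map.r_squared, spacing, out_dir / f"{stem}_r2.nii")
    _save_nifti(t2map.valid.astype(float), spacing, out_dir / f"{stem}_valid.nii")
    side = out_dir / f"{stem}.json"
    side.write_text(json.dumps(t2map.provenance, indent=2))
    return side


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

def save_laminar_summaries(
    summaries: Iterable[LaminarSummary], path: str | Path,
    knee_id: str = "phantom", visit: str = "baseline",
) -> Path:
    rows = [
        {
            "knee_id": knee_id, "visit": visit, "plate": s.plate, "layer": s.layer,
            "mean_t2_ms": s.mean_t2_ms, "n_valid": s.n_voxels_valid, "n_total": s.n_voxels_total,
        }
        for s in summaries
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    violations = validate_cohort(df)
    if violations:
        raise ValidationError("; ".join(violations))
    return df


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Schema and uniqueness checks for a cohort table; returns violations."""
    problems: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
        return problems
    dup = df.duplicated(subset=["subject_id", "visit", "plate", "layer"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        problems.append(f"duplicate (subject, visit, plate, layer) rows at index {rows}")
    bad_visit = set(df["visit"].unique()) - {"baseline", "year1"}
    if bad_visit:
        problems.append(f"unknown visit labels: {sorted(bad_visit)}")
    bad_layer = set(df["layer"].unique()) - {"deep", "superficial"}
    if bad_layer:
        problems.append(f"unknown layer labels: {sorted(bad_layer)}")
    multi = df.groupby("subject_id")["group"].nunique()
    if (multi > 1).any():
        problems.append(f"subjects in multiple groups: {multi[multi > 1].index.tolist()[:10]}")
    base = df[df["visit"] == "baseline"]
    fu = df[df["visit"] == "year1"]
    orphans = set(fu["subject_id"]) - set(base["subject_id"])
    if orphans:
        problems.append(f"follow-up rows without baseline: {sorted(orphans)[:10]}")
    if not np.isfinite(df["t2_ms"].to_numpy(dtype=float)).all():
        problems.append("non-finite t2_ms values present")
    return problems
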