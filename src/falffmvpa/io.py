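"""Reading and writing cohorts: NIfTI-1 volumes, TSV tables, manifests.

A cohort on disk is a directory with one 4D BOLD NIfTI and one confound TSV
per subject, a shared 3D mask NIfTI, a phenotype CSV and a ``manifest.json``
listing all paths in subject order.  TR is carried in the NIfTI header
(pixdim[4]) and checked on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import SubjectScan

__all__ = ["read_subject", "write_cohort", "load_cohort"]


def _affine(voxel_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4) * voxel_mm
    aff[3, 3] = 1.0
    return aff


def read_subject(
    volume_path, mask_path, confounds_path, tr_seconds: float | None = None
) -> SubjectScan:
    """Load one subject's scan, applying the mask and checking metadata.

    TR is taken from the volume header unless ``tr_seconds`` overrides it;
    a missing/zero header TR without an override is an error.  Grid
    mismatch between volume and mask raises with both shapes named.
    """
    img = nib.load(str(volume_path))
    series = np.asarray(img.get_fdata(), dtype=float)
    if series.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 4D volume, got shape {series.shape}")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    if mask.shape != series.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid {series.shape[:3]}"
        )
    tr = float(img.header["pixdim"][4])
    if tr_seconds is not None:
        tr = float(tr_seconds)
    elif tr <= 0:
        raise ValueError(f"{volume_path}: no TR in header; pass tr_seconds explicitly")
    confounds = pd.read_csv(confounds_path, sep="\t")
    series = np.where(mask[..., None], series, 0.0)
    return SubjectScan(series=series, mask=mask, tr_seconds=tr, confounds=confounds)


def write_cohort(scans, phenotype, out_dir, voxel_mm: float = 3.0) -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(voxel_mm)
    mask_path = out / "mask.nii"
    nib.Nifti1Image(scans[0].mask.astype(np.uint8), aff).to_filename(str(mask_path))
    entries = []
    for scan, sid in zip(scans, phenotype["subject_id"]):
        img = nib.Nifti1Image(scan.series.astype(np.float32), aff)
        img.header["pixdim"][4] = scan.tr_seconds
        vol_path = out / f"{sid}_bold.nii"
        img.to_filename(str(vol_path))
        conf_path = out / f"{sid}_confounds.tsv"
        scan.confounds.to_csv(conf_path, sep="\t", index=False)
        entries.append(
            {
                "subject_id": sid,
                "volume": vol_path.name,
                "confounds": conf_path.name,
                "tr_seconds": scan.tr_seconds,
            }
        )
    pheno_path = out / "phenotype.csv"
    phenotype.to_csv(pheno_path, index=False)
    manifest = {
        "mask": mask_path.name,
        "phenotype": pheno_path.name,
        "subjects": entries,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(manifest_path):
    """Load a written cohort back as (scans, phenotype) in manifest order."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    phenotype = pd.read_csv(root / manifest["phenotype"])
    scans = []
    for entry in manifest["subjects"]:
        scans.append(
            read_subject(
                root / entry["volume"],
                root / manifest["mask"],
                root / entry["confounds"],
                tr_seconds=entry.get("tr_seconds"),
            )
        )
    order = list(phenotype["subject_id"])
    got = [e["subject_id"] for e in manifest["subjects"]]
    if order != got:
        raise ValueError("manifest subject order does not match phenotype table")
    return scans, phenotype
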