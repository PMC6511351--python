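"""NIfTI / TSV / manifest I/O (nibabel-backed)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import MOTION_COLUMNS, AtlasNetworks, Bold4D, GrayMatterMap, MotionTrace


def save_bold(run: Bold4D, path: str | Path) -> None:
    img = nib.Nifti1Image(run.data, run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr))
    nib.save(img, str(path))


def load_bold(path: str | Path, tr: float | None = None) -> Bold4D:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = tr if tr is not None else float(zooms[3]) if len(zooms) > 3 else None
    if not tr:
        raise ValueError(f"{path}: TR not recorded in header; pass tr explicitly")
    return Bold4D(data=np.asarray(img.dataobj), affine=img.affine, tr=float(tr))


def save_gm_map(gm: GrayMatterMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(gm.data.astype(np.float32), gm.affine), str(path))


def load_gm_map(path: str | Path) -> GrayMatterMap:
    img = nib.load(str(path))
    return GrayMatterMap(data=np.asarray(img.dataobj, dtype=float), affine=img.affine)


def save_atlas(atlas: AtlasNetworks, labels_path: str | Path, assign_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(labels_path))
    pd.DataFrame(
        {"roi_id": list(atlas.assignment), "network": list(atlas.assignment.values())}
    ).to_csv(assign_path, sep="\t", index=False)


def load_atlas(labels_path: str | Path, assign_path: str | Path) -> AtlasNetworks:
    img = nib.load(str(labels_path))
    table = pd.read_csv(assign_path, sep="\t")
    assignment = dict(zip(table["roi_id"].astype(int), table["network"].astype(str)))
    return AtlasNetworks(
        labels=np.asarray(img.dataobj).astype(np.int16),
        assignment=assignment,
        affine=img.affine,
    )


def load_motion(path: str | Path) -> MotionTrace:
    table = pd.read_csv(path, sep="\t")
    if tuple(table.columns) != MOTION_COLUMNS:
        raise ValueError(f"{path}: expected motion columns {MOTION_COLUMNS}")
    return MotionTrace(table=table)


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    manifest["_root"] = str(path.parent)
    return manifest
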