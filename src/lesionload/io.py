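"""Readers and writers: NIfTI-1 volumes, CSV tables, JSON catalogues.

FA maps, the skeleton mask and the tract atlas travel as NIfTI-1; subject
tables as CSV with documented headers; cluster catalogues and model
reports as JSON.  Voxel coordinates in exported artefacts are 0-based
array indices, with world coordinates available through the NIfTI affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import SkeletonGeometry, SkeletonImage, TractAtlas
from .clusters import Cluster, ClusterSet
from .simulate import CohortBundle, SimulationConfig

__all__ = [
    "write_cohort",
    "read_skeleton_cohort",
    "catalogue_to_json",
    "catalogue_from_json",
    "save_json",
]


def _to_nifti(volume: np.ndarray, affine: np.ndarray, dtype) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(volume, dtype=dtype), affine)


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> Path:
    """Serialize a simulated cohort to disk (NIfTI + CSV + YAML)."""
    outdir = Path(outdir)
    (outdir / "fa").mkdir(parents=True, exist_ok=True)
    geom = bundle.geometry
    _to_nifti(geom.mask, geom.affine, np.uint8).to_filename(str(outdir / "skeleton.nii"))
    _to_nifti(bundle.atlas.labels, geom.affine, np.int16).to_filename(
        str(outdir / "atlas.nii")
    )
    bundle.atlas.table.to_csv(outdir / "atlas_labels.csv", index=False)
    for im in bundle.images:
        _to_nifti(im.to_volume(), geom.affine, np.float32).to_filename(
            str(outdir / "fa" / f"{im.subject_id}_fa.nii")
        )
    bundle.covariates.to_csv(outdir / "covariates.csv", index=False)
    bundle.cytokines.to_csv(outdir / "cytokines.csv", index=False)
    bundle.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    bundle.truth["burden"].to_csv(outdir / "truth_burden.csv", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_jsonable(bundle.config.to_dict()), fh, sort_keys=False)
    return outdir


def read_skeleton_cohort(
    fa_dir: str | Path,
    skeleton_path: str | Path,
    atlas_path: str | Path,
    atlas_table_path: str | Path,
) -> tuple[list[SkeletonImage], SkeletonGeometry, TractAtlas]:
    """Load a cohort of skeletonized FA volumes plus skeleton and atlas.

    Every FA volume must share the skeleton's shape and affine, and FA
    must lie in [0, 1] on the skeleton; violations are reported with the
    offending filename.  Atlas labels absent from the label table are
    rejected as orphans.
    """
    skel_img = nib.load(str(skeleton_path))
    mask = np.asarray(skel_img.dataobj) > 0
    voxel_size = tuple(float(z) for z in skel_img.header.get_zooms()[:3])
    geometry = SkeletonGeometry(mask=mask, voxel_size=voxel_size, affine=skel_img.affine)

    atlas_img = nib.load(str(atlas_path))
    if atlas_img.shape != skel_img.shape:
        raise ValueError(f"atlas shape mismatch: {atlas_path}")
    table = pd.read_csv(atlas_table_path)
    atlas = TractAtlas(
        labels=np.rint(np.asarray(atlas_img.dataobj)).astype(np.int32), table=table
    )

    images: list[SkeletonImage] = []
    for path in sorted(Path(fa_dir).glob("*.nii*")):
        img = nib.load(str(path))
        if img.shape != skel_img.shape:
            raise ValueError(f"volume shape mismatch: {path.name}")
        if not np.allclose(img.affine, skel_img.affine, atol=1e-4):
            raise ValueError(f"volume affine mismatch: {path.name}")
        vol = np.asarray(img.dataobj, dtype=float)
        values = geometry.extract(vol)
        if np.any((values < -1e-6) | (values > 1 + 1e-6)):
            raise ValueError(f"FA outside [0, 1] on skeleton: {path.name}")
        sid = path.name.split(".nii")[0].removesuffix("_fa")
        images.append(SkeletonImage(sid, np.clip(values, 0.0, 1.0), geometry))
    return images, geometry, atlas


def catalogue_to_json(catalogue: ClusterSet, path: str | Path) -> None:
    payload = {
        "provenance": _jsonable(catalogue.provenance),
        "clusters": [
            {
                "id": c.id,
                "tract_label": c.tract_label,
                "tract_name": c.tract_name,
                "direction": c.direction,
                "extent": c.extent,
                "voxels": c.voxels.tolist(),
            }
            for c in catalogue.clusters
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def catalogue_from_json(path: str | Path) -> ClusterSet:
    payload = json.loads(Path(path).read_text())
    clusters = [
        Cluster(
            id=c["id"],
            tract_label=int(c["tract_label"]),
            tract_name=c["tract_name"],
            direction=c["direction"],
            voxels=np.asarray(c["voxels"], dtype=np.int64),
        )
        for c in payload["clusters"]
    ]
    return ClusterSet(clusters=clusters, provenance=payload.get("provenance", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, SimulationConfig):
        return _jsonable(obj.to_dict())
    return obj


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
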