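"""Containers for skeletonized scalar maps and tract-label atlases.

A TBSS-style analysis lives on a sparse set of voxels (the white-matter
skeleton) embedded in a regular 3D grid.  ``SkeletonGeometry`` holds the
binary mask and grid metadata once per cohort; each subject's FA map is a
flat vector of on-skeleton values (``SkeletonImage``) that can be embedded
back into the volume for I/O or connected-component work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SkeletonGeometry", "SkeletonImage", "TractAtlas"]


@dataclass
class SkeletonGeometry:
    """Binary skeleton mask plus grid geometry, shared across a cohort.

    Parameters
    ----------
    mask : bool array, shape ``grid_shape``
        True on skeleton voxels.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : (4, 4) array, optional
        Voxel-to-world transform; defaults to a diagonal scaling by
        ``voxel_size``.
    """

    mask: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("skeleton mask must be 3D")
        if not self.mask.any():
            raise ValueError("skeleton mask is empty")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.flat_index = np.flatnonzero(self.mask.ravel())
        self.coords = np.array(np.nonzero(self.mask)).T  # (n_voxels, 3)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.flat_index.size)

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an on-skeleton vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} on-skeleton values, got {values.shape[-1]}"
            )
        vol = np.full(self.mask.size, fill, dtype=values.dtype)
        vol[self.flat_index] = values
        return vol.reshape(self.shape)

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a full 3D volume to the on-skeleton vector."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(f"volume shape {volume.shape} != grid {self.shape}")
        return volume.ravel()[self.flat_index]


@dataclass
class SkeletonImage:
    """One subject's scalar map sampled on the skeleton."""

    subject_id: str
    data: np.ndarray  # 1D, one value per on-skeleton voxel
    geometry: SkeletonGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1 or self.data.size != self.geometry.n_voxels:
            raise ValueError(
                f"{self.subject_id}: data length {self.data.size} does not match "
                f"skeleton ({self.geometry.n_voxels} voxels)"
            )

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        return self.geometry.embed(self.data, fill=fill)


def stack_images(images: list[SkeletonImage]) -> np.ndarray:
    """Stack cohort images into an (n_subjects, n_voxels) matrix."""
    if not images:
        raise ValueError("no images to stack")
    geom = images[0].geometry
    for im in images:
        if im.geometry is not geom and not np.array_equal(im.geometry.mask, geom.mask):
            raise ValueError(f"{im.subject_id}: skeleton mask differs across cohort")
    return np.vstack([im.data for im in images])


@dataclass
class TractAtlas:
    """Integer tract-label volume plus its label table.

    The table must have columns ``label`` (int, nonzero) and ``name``.
    Label 0 is background.
    """

    labels: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.table["label"].astype(int))
        orphans = sorted(present - known)
        if orphans:
            raise ValueError(f"atlas labels missing from label table: {orphans}")

    def name_of(self, label: int) -> str:
        row = self.table.loc[self.table["label"] == label, "name"]
        if row.empty:
            raise KeyError(f"unknown tract label {label}")
        return str(row.iloc[0])

    def labels_on_skeleton(self, geometry: SkeletonGeometry) -> np.ndarray:
        if self.labels.shape != geometry.shape:
            raise ValueError(
                f"atlas shape {self.labels.shape} != skeleton grid {geometry.shape}"
            )
        return geometry.extract(self.labels)
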