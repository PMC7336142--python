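"""Atlas-based compression of voxel-wise gray-matter maps to parcel volumes.

All statistics and age prediction in this package operate on a fixed
673-parcel representation of gray matter: 600 cortical, 36 subcortical and
37 cerebellar parcels.  This module provides

* :class:`AtlasLabelMap` — a 3-D integer label grid plus a label table
  assigning each label a parcel id and a compartment,
* :func:`build_default_atlas` — a synthetic contiguous-region tessellation
  with exactly that 600/36/37 compartment split, used wherever the real
  (separately distributed) anatomical label images are not available,
* :func:`aggregate_voxels_to_parcels` / :func:`compress_cohort` — the
  voxel-to-parcel reduction.

Modulated gray-matter segments represent actual tissue volume, so the
default reduction is ``sum`` scaled by the voxel volume (yielding mm^3 when
the map is a modulated segment); ``mean`` is offered for sensitivity checks.
Label images and gray-matter maps are read and written as NIfTI-1 via
nibabel; the label table is a three-column TSV (label, parcel_id,
compartment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import ParcelMatrix

#: Compartment sizes of the default 673-parcel atlas.
DEFAULT_COMPARTMENT_COUNTS = {"cortical": 600, "subcortical": 36, "cerebellar": 37}

_COMPARTMENT_PREFIX = {"cortical": "CTX", "subcortical": "SUB", "cerebellar": "CBL"}


@dataclass
class AtlasLabelMap:
    """3-D integer label grid (0 = background) with label metadata.

    ``label_table`` has columns ``label`` (positive int), ``parcel_id`` and
    ``compartment``; its row order defines the parcel order of every
    aggregated vector and :class:`ParcelMatrix`.
    """

    labels: np.ndarray
    label_table: pd.DataFrame
    voxel_volume: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas label grid must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas label grid must be integer-valued")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        required = {"label", "parcel_id", "compartment"}
        if not required.issubset(self.label_table.columns):
            raise ValueError(f"label table needs columns {sorted(required)}")
        table_labels = set(int(x) for x in self.label_table["label"])
        grid_labels = set(int(x) for x in np.unique(self.labels)) - {0}
        if grid_labels - table_labels:
            raise ValueError(
                f"labels present in grid but absent from table: {sorted(grid_labels - table_labels)[:5]}"
            )
        if table_labels - grid_labels:
            raise ValueError(
                f"labels in table but without any voxel in grid: {sorted(table_labels - grid_labels)[:5]}"
            )
        if self.label_table["parcel_id"].duplicated().any():
            raise ValueError("parcel ids in the label table must be unique")

    @property
    def n_parcels(self) -> int:
        return len(self.label_table)

    def voxel_counts(self) -> np.ndarray:
        """Voxel count per label, in label-table order."""
        counts = np.bincount(self.labels.ravel(), minlength=int(self.labels.max()) + 1)
        return counts[self.label_table["label"].to_numpy()]

    def compartment_counts(self) -> dict[str, int]:
        return self.label_table["compartment"].value_counts().to_dict()


def build_default_atlas(
    grid_shape: tuple[int, int, int] = (28, 28, 28),
    seed: int = 0,
    compartment_counts: dict[str, int] | None = None,
    voxel_volume: float = 1.0,
) -> AtlasLabelMap:
    """Build the synthetic default atlas: a random contiguous tessellation.

    An ellipsoidal "brain" mask inscribed in ``grid_shape`` is partitioned
    into nearest-seed (Voronoi) regions around randomly placed seed voxels —
    one per parcel, so every label has at least one voxel, and regions are
    connected because the mask is convex.  The label count and compartment
    split default to the 600 cortical / 36 subcortical / 37 cerebellar
    parcels used throughout; deterministic given ``seed``.
    """
    counts = dict(compartment_counts or DEFAULT_COMPARTMENT_COUNTS)
    n_parcels = sum(counts.values())
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 1 for s in grid_shape):
        raise ValueError("grid_shape must be three positive extents")

    ii, jj, kk = np.indices(grid_shape, dtype=float)
    center = [(s - 1) / 2.0 for s in grid_shape]
    semi = [max(s / 2.0 - 0.5, 0.5) for s in grid_shape]
    mask = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    ) <= 1.0
    n_in_mask = int(mask.sum())
    if n_in_mask < n_parcels:
        raise ValueError(
            f"grid {grid_shape} has only {n_in_mask} voxels inside the brain mask; "
            f"at least {n_parcels} are required (one per parcel)"
        )

    rng = np.random.default_rng(seed)
    coords = np.column_stack(np.nonzero(mask))
    seed_rows = rng.choice(n_in_mask, size=n_parcels, replace=False)
    tree = cKDTree(coords[seed_rows])
    _, assignment = tree.query(coords, k=1)

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[tuple(coords.T)] = assignment + 1

    rows = []
    label = 1
    for compartment in ("cortical", "subcortical", "cerebellar"):
        for i in range(counts.get(compartment, 0)):
            rows.append(
                {
                    "label": label,
                    "parcel_id": f"{_COMPARTMENT_PREFIX[compartment]}_{i + 1:03d}",
                    "compartment": compartment,
                }
            )
            label += 1
    table = pd.DataFrame(rows)
    return AtlasLabelMap(labels=labels, label_table=table, voxel_volume=voxel_volume)


def aggregate_voxels_to_parcels(
    voxel_map: np.ndarray, atlas: AtlasLabelMap, reduction: str = "sum"
) -> np.ndarray:
    """Reduce a voxel map to one value per parcel, in label-table order.

    ``sum`` is additionally scaled by the atlas voxel volume so that the
    result is a volume; ``mean`` is the plain per-label average.  Background
    (label 0) is excluded.
    """
    voxel_map = np.asarray(voxel_map, dtype=float)
    if voxel_map.shape != atlas.labels.shape:
        raise ValueError(
            f"voxel map shape {voxel_map.shape} does not match atlas grid {atlas.labels.shape}"
        )
    if reduction not in ("sum", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}; use 'sum' or 'mean'")

    flat_labels = atlas.labels.ravel()
    minlength = int(flat_labels.max()) + 1
    sums = np.bincount(flat_labels, weights=voxel_map.ravel(), minlength=minlength)
    counts = np.bincount(flat_labels, minlength=minlength)

    order = atlas.label_table["label"].to_numpy()
    empty = counts[order] == 0
    if empty.any():
        bad = atlas.label_table.loc[empty, "parcel_id"].iloc[0]
        raise ValueError(f"label for parcel {bad!r} has zero voxels in the atlas grid")
    if reduction == "sum":
        return sums[order] * atlas.voxel_volume
    return sums[order] / counts[order]


def compress_cohort(voxel_maps, atlas: AtlasLabelMap, reduction: str = "sum") -> ParcelMatrix:
    """Aggregate a batch of subjects' voxel maps into a :class:`ParcelMatrix`.

    ``voxel_maps`` is an iterable of ``(subject_id, voxel_map)`` pairs or a
    mapping ``subject_id -> voxel_map``; row order follows input order.
    """
    if hasattr(voxel_maps, "items"):
        items = list(voxel_maps.items())
    else:
        items = list(voxel_maps)
    rows = []
    subject_ids = []
    for subject_id, voxel_map in items:
        try:
            rows.append(aggregate_voxels_to_parcels(voxel_map, atlas, reduction))
        except Exception as e:
            raise ValueError(f"aggregation failed for subject {subject_id!r}: {e}") from e
        subject_ids.append(str(subject_id))
    if not rows:
        raise ValueError("no voxel maps supplied")
    return ParcelMatrix(np.vstack(rows), list(atlas.label_table["parcel_id"]), subject_ids)


# ---------------------------------------------------------------------------
# NIfTI / TSV interfaces


def save_atlas(atlas: AtlasLabelMap, image_path, table_path) -> None:
    affine = np.diag([atlas.voxel_volume ** (1 / 3)] * 3 + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int32), affine), str(image_path))
    atlas.label_table.to_csv(table_path, sep="\t", index=False)


def load_atlas(image_path, table_path, voxel_volume: float | None = None) -> AtlasLabelMap:
    img = nib.load(str(image_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    if voxel_volume is None:
        voxel_volume = float(abs(np.linalg.det(img.affine[:3, :3])))
    return AtlasLabelMap(labels=labels, label_table=table, voxel_volume=voxel_volume)


def load_voxel_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_voxel_map(voxel_map: np.ndarray, path, voxel_volume: float = 1.0) -> None:
    affine = np.diag([voxel_volume ** (1 / 3)] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(voxel_map, dtype=np.float32), affine), str(path))


def compress_directory(gm_dir, atlas: AtlasLabelMap, reduction: str = "sum") -> ParcelMatrix:
    """Compress every ``*.nii``/``*.nii.gz`` map in a directory (sorted order)."""
    paths = sorted(
        p for p in Path(gm_dir).iterdir() if p.name.endswith((".nii", ".nii.gz"))
    )
    if not paths:
        raise ValueError(f"no NIfTI gray-matter maps found in {gm_dir}")
    items = [(p.name.split(".")[0], load_voxel_map(p)) for p in paths]
    return compress_cohort(items, atlas, reduction)
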