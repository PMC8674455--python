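"""Volumetric containers and NIfTI-1 input/output.

Group-level inference operates on a stack of per-subject contrast images
(one 3-D volume per subject, in BOLD percent-signal-change units) restricted
to a binary analysis mask.  This module holds the in-memory containers and
the round-trip to NIfTI-1 files plus TSV decision tables.

Conventions: volumes are written float32 with NaN outside the mask (so that
viewers render the background transparently); voxel indices in tables are
0-based; world coordinates come from the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

#: Cap applied to log posterior odds so maps stay finite and viewable.
#: logit(p) = 38 corresponds to 1 - p at the edge of float64 resolution.
LPO_CAP = 38.0

#: Affine agreement tolerance when stacking subject volumes.
AFFINE_ATOL = 1e-4


class GeometryError(ValueError):
    """Volumes that do not share a common shape/affine."""


class DataError(ValueError):
    """Ill-formed voxel data (non-finite in-mask values, length mismatch...)."""


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape and voxel-to-world mapping of a 3-D volume."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise GeometryError(f"shape must be 3 positive ints, got {self.shape}")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]

    def matches(self, other: "VolumeGeometry", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class GroupStack:
    """Subjects x voxels matrix of contrast values inside a mask.

    ``data[i, j]`` is subject i's contrast value (PSC) at the j-th in-mask
    voxel; column order follows C-order flattening of the mask volume.
    """

    data: np.ndarray
    mask: np.ndarray
    geometry: VolumeGeometry
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise GeometryError("mask shape does not match geometry")
        n_vox = int(self.mask.sum())
        if n_vox == 0:
            raise DataError("mask is empty")
        if self.data.ndim != 2 or self.data.shape[1] != n_vox:
            raise DataError(
                f"data must be subjects x {n_vox} in-mask voxels, "
                f"got shape {self.data.shape}"
            )
        if self.data.shape[0] < 2:
            raise DataError("need at least 2 subjects")
        if not np.isfinite(self.data).all():
            raise DataError("non-finite values inside the mask")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:04d}" for i in range(self.data.shape[0])]
        if len(self.subject_ids) != self.data.shape[0]:
            raise DataError("subject_ids length does not match data rows")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def voxel_indices(self) -> np.ndarray:
        """(n_voxels, 3) array of i,j,k indices of in-mask voxels."""
        return np.array(np.nonzero(self.mask)).T

    def subset(self, rows: np.ndarray) -> "GroupStack":
        """New stack restricted to the given subject rows."""
        rows = np.asarray(rows)
        return GroupStack(
            data=self.data[rows],
            mask=self.mask,
            geometry=self.geometry,
            subject_ids=[self.subject_ids[i] for i in rows],
        )


def _load_volume(path) -> tuple[np.ndarray, VolumeGeometry]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj, dtype=float)
    if arr.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D volume, got ndim={arr.ndim}")
    return arr, VolumeGeometry(arr.shape, img.affine)


def load_mask(path) -> tuple[np.ndarray, VolumeGeometry]:
    """Load a binary mask volume; values must be 0/1 (NaN counts as 0)."""
    arr, geom = _load_volume(path)
    arr = np.nan_to_num(arr, nan=0.0)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise DataError(f"{path}: mask is not binary (values {vals[:5]}...)")
    return arr.astype(bool), geom


def load_group_stack(paths, mask_path) -> GroupStack:
    """Stack per-subject contrast volumes into a masked subjects x voxels matrix.

    All volumes must share the mask's shape and affine (tolerance
    ``AFFINE_ATOL``); any non-finite value inside the mask is an error naming
    the offending file.
    """
    mask, geom = load_mask(mask_path)
    rows = []
    ids = []
    for path in paths:
        arr, g = _load_volume(path)
        if not geom.matches(g):
            raise GeometryError(f"{path}: shape/affine differs from mask geometry")
        vals = arr[mask]
        if not np.isfinite(vals).all():
            raise DataError(f"{path}: non-finite values inside the mask")
        rows.append(vals)
        ids.append(str(path))
    return GroupStack(
        data=np.vstack(rows), mask=mask, geometry=geom, subject_ids=ids
    )


def write_map(values, mask, geometry: VolumeGeometry, path, inf_cap: float = LPO_CAP):
    """Write a per-voxel vector as a float32 NIfTI volume, NaN outside the mask.

    Infinite values (e.g. log posterior odds at p = 1) are clipped to
    ``+/- inf_cap`` so the stored map is finite.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geometry.shape:
        raise GeometryError("mask shape does not match geometry")
    if mask.sum() == 0:
        raise DataError("mask is empty")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size != mask.sum():
        raise DataError(
            f"values length {values.size} != in-mask voxel count {mask.sum()}"
        )
    values = np.clip(values, -inf_cap, inf_cap)
    vol = np.full(geometry.shape, np.nan, dtype=np.float32)
    vol[mask] = values.astype(np.float32)
    img = nib.Nifti1Image(vol, geometry.affine)
    nib.save(img, str(path))
    return path


def read_map(path) -> tuple[np.ndarray, np.ndarray, VolumeGeometry]:
    """Read a map written by :func:`write_map`.

    Returns (in-mask values, mask, geometry) where the mask is the set of
    finite voxels.
    """
    arr, geom = _load_volume(path)
    mask = np.isfinite(arr)
    return arr[mask], mask, geom


_LABEL_NAMES = {1: "activated", -1: "deactivated", 2: "not_activated", 0: "low_confidence"}


def write_decision_table(decisions, path) -> pd.DataFrame:
    """Serialize a per-voxel decision table plus a one-row label summary.

    Writes a TSV with voxel index, world coordinates, label, the three ROPE
    posterior probabilities, LPOs and the posterior moments, and a companion
    ``*_summary.tsv`` with counts and percentages per label (percentages sum
    to 100).
    """
    post = decisions.posterior
    probs = decisions.probs
    stack_mask = post.mask
    geom = post.geometry
    ijk = np.array(np.nonzero(stack_mask)).T
    xyz = geom.voxel_to_world(ijk)
    labels = [_LABEL_NAMES[int(c)] for c in decisions.label]
    table = pd.DataFrame(
        {
            "voxel_index": np.arange(len(labels)),
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "label": labels,
            "p_act": probs.p_act,
            "p_deact": probs.p_deact,
            "p_null": probs.p_null,
            "lpo_act": probs.lpo_act,
            "lpo_deact": probs.lpo_deact,
            "lpo_null": probs.lpo_null,
            "posterior_mean": post.post_mean,
            "posterior_sd": post.post_sd,
        }
    )
    table.to_csv(path, sep="\t", index=False)

    order = ["activated", "deactivated", "not_activated", "low_confidence"]
    counts = {name: labels.count(name) for name in order}
    total = len(labels)
    summary = pd.DataFrame(
        [
            {
                **{f"n_{k}": v for k, v in counts.items()},
                **{f"pct_{k}": 100.0 * v / total for k, v in counts.items()},
                "n_total": total,
            }
        ]
    )
    summary_path = str(path).replace(".tsv", "") + "_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    return table
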