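"""NIfTI I/O, analysis masking, and the subjects x voxels data matrix.

This is the hinge between image space and matrix space: every subject's
3-D gray-matter map is flattened over a common mask into one row of a
:class:`GMDataMatrix`, and any row of that matrix (or any ICA source) can
be folded back into a volume with :func:`unflatten`.  Flattening is
lossless on the mask and rows are kept in subject-table order, because the
statistics stage joins on that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    CohortConsistencyError,
    DegenerateMaskError,
    DimensionMismatchError,
)

_AFFINE_TOL = 1e-4


@dataclass
class GMVolume:
    """One subject's 3-D gray-matter map with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionMismatchError(
                f"volume for {self.subject_id!r} is {self.data.ndim}-D, expected 3-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise CohortConsistencyError(
                f"volume for {self.subject_id!r} contains non-finite voxels"
            )


@dataclass
class GMDataMatrix:
    """Subjects x masked-voxels matrix plus the bookkeeping to invert it.

    ``values[i, j]`` is subject ``row_ids[i]`` at the j-th in-mask voxel,
    where columns enumerate ``np.flatnonzero(mask)`` in C order.
    """

    values: np.ndarray  # (N, V)
    row_ids: list[str]
    mask: np.ndarray  # 3-D boolean
    affine: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def mask_index(self) -> np.ndarray:
        """(V, 3) array mapping column -> 3-D voxel coordinate."""
        return np.argwhere(self.mask)

    def unflatten(self, vector: np.ndarray, subject_id: str = "") -> GMVolume:
        return unflatten(vector, self.mask, self.affine, subject_id=subject_id)


def load_volume(path: str | Path, subject_id: str = "") -> GMVolume:
    path = Path(path)
    if not path.exists():
        raise CohortConsistencyError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return GMVolume(data=data, affine=img.affine, subject_id=subject_id or path.name)


def save_volume(volume: GMVolume, path: str | Path) -> Path:
    """Write as NIfTI-1 preserving the array dtype (bitwise round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_data_dtype(volume.data.dtype)
    nib.save(img, str(path))
    return path


def _volume_paths_by_id(
    volume_paths: Iterable[str | Path] | str | Path,
) -> dict[str, Path]:
    if isinstance(volume_paths, (str, Path)) and Path(volume_paths).is_dir():
        paths = sorted(Path(volume_paths).glob("*.nii*"))
    else:
        paths = [Path(p) for p in volume_paths]  # type: ignore[union-attr]
    by_id = {}
    for p in paths:
        stem = p.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        by_id[stem] = p
    return by_id


def load_cohort(
    volume_paths: Iterable[str | Path] | str | Path,
    subject_table: pd.DataFrame,
) -> list[GMVolume]:
    """Load one volume per subject-table row, in table order.

    ``volume_paths`` is a directory or an explicit list of files; files are
    matched to rows by filename stem == ``subject_id``.  All volumes must
    share grid shape and affine (within 1e-4 per affine entry).
    """
    by_id = _volume_paths_by_id(volume_paths)
    volumes: list[GMVolume] = []
    for sid in subject_table["subject_id"].astype(str):
        if sid not in by_id:
            raise CohortConsistencyError(
                f"no volume file found for subject_id {sid!r}"
            )
        volumes.append(load_volume(by_id[sid], subject_id=sid))
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape:
            raise CohortConsistencyError(
                f"grid shape mismatch: {v.subject_id!r} has {v.data.shape}, "
                f"{ref.subject_id!r} has {ref.data.shape}"
            )
        if np.max(np.abs(v.affine - ref.affine)) > _AFFINE_TOL:
            raise CohortConsistencyError(
                f"affine mismatch between {v.subject_id!r} and {ref.subject_id!r}"
            )
    return volumes


def make_mask(
    volumes: Sequence[GMVolume],
    threshold_fraction: float = 0.2,
    explicit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Across-subject mean-intensity mask.

    A voxel is kept when the across-subject mean exceeds
    ``threshold_fraction`` times the grand mean of nonzero voxels of the
    mean image; an explicit mask, when given, is intersected on top.
    """
    if not volumes:
        raise DegenerateMaskError("no volumes given")
    if not 0 <= threshold_fraction <= 1:
        raise DegenerateMaskError("threshold_fraction must lie in [0, 1]")
    mean_img = np.mean([v.data for v in volumes], axis=0)
    nonzero = mean_img[mean_img > 0]
    if nonzero.size == 0:
        raise DegenerateMaskError("all volumes are zero; mask would be empty")
    if threshold_fraction == 0:
        mask = np.ones_like(mean_img, dtype=bool)
    else:
        mask = mean_img > threshold_fraction * nonzero.mean()
    if explicit_mask is not None:
        if explicit_mask.shape != mask.shape:
            raise DimensionMismatchError(
                "explicit mask shape does not match the volume grid"
            )
        mask &= explicit_mask.astype(bool)
    if not mask.any():
        raise DegenerateMaskError("mask is empty after thresholding")
    return mask


def build_matrix(
    volumes: Sequence[GMVolume], mask: np.ndarray
) -> GMDataMatrix:
    """Stack masked voxels of each volume into the N x V analysis matrix."""
    if not np.asarray(mask, dtype=bool).any():
        raise DegenerateMaskError("mask is empty")
    mask = np.asarray(mask, dtype=bool)
    ref = volumes[0]
    if mask.shape != ref.data.shape:
        raise DimensionMismatchError("mask shape does not match volumes")
    values = np.stack([v.data[mask].astype(float) for v in volumes])
    return GMDataMatrix(
        values=values,
        row_ids=[v.subject_id for v in volumes],
        mask=mask,
        affine=ref.affine.copy(),
    )


def unflatten(
    vector: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    subject_id: str = "",
) -> GMVolume:
    """Fold a masked-voxel vector back into a volume (zeros off-mask)."""
    mask = np.asarray(mask, dtype=bool)
    vector = np.asarray(vector, dtype=float).ravel()
    n_mask = int(mask.sum())
    if vector.size != n_mask:
        raise DimensionMismatchError(
            f"vector has {vector.size} values but mask has {n_mask} voxels"
        )
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = vector
    if affine is None:
        affine = np.eye(4)
    return GMVolume(data=vol, affine=affine, subject_id=subject_id)
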