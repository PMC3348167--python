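"""NIfTI input/output and the cohort data container.

Volumes are per-subject gray-matter density maps produced upstream by
segmentation, spatial normalisation and smoothing.  This module flattens a
stack of such maps into a subject-by-voxel matrix under an analysis mask and
writes per-voxel score maps back into image space.

Voxel indexing convention: flat voxel indices are 0-based and enumerate the
in-mask voxels in row-major (C) order over the 3-D grid.  Every module in the
package uses this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BrainMask",
    "Cohort",
    "load_gm_maps",
    "make_mask",
    "save_score_map",
    "read_subject_table",
]

#: group vocabulary -> class code (young is the positive class throughout)
GROUP_CODES = {"young": 1, "old": -1}


@dataclass(frozen=True)
class BrainMask:
    """Analysis mask linking flat voxel indices to 3-D grid coordinates.

    Flat index ``j`` (0-based) refers to the ``j``-th in-mask voxel in
    row-major order.  ``affine`` is carried through to written images but is
    never interpreted.
    """

    in_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.in_mask, dtype=bool)
        object.__setattr__(self, "in_mask", m)
        if m.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {m.shape}")
        if not m.any():
            raise ValueError("mask is empty: no voxels survive")
        # row-major positions of in-mask voxels in the raveled grid
        object.__setattr__(self, "_ravel_pos", np.flatnonzero(m.ravel(order="C")))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.in_mask.shape)

    @property
    def n_voxels(self) -> int:
        return int(self._ravel_pos.size)

    def unflatten(self, flat_index: np.ndarray | int) -> np.ndarray:
        """Map flat voxel index/indices to (…, 3) grid coordinates."""
        j = np.asarray(flat_index)
        if np.any(j < 0) or np.any(j >= self.n_voxels):
            raise IndexError("flat voxel index out of range")
        coords = np.unravel_index(self._ravel_pos[j], self.grid_shape)
        return np.stack(coords, axis=-1)

    def flatten(self, coords: np.ndarray) -> np.ndarray:
        """Map (…, 3) grid coordinates of in-mask voxels to flat indices."""
        coords = np.asarray(coords)
        pos = np.ravel_multi_index(tuple(coords.reshape(-1, 3).T), self.grid_shape)
        j = np.searchsorted(self._ravel_pos, pos)
        bad = (j >= self.n_voxels) | (self._ravel_pos[np.minimum(j, self.n_voxels - 1)] != pos)
        if np.any(bad):
            raise IndexError("coordinate not inside the mask")
        return j.reshape(coords.shape[:-1])

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3-D volume to the length-V vector of in-mask values."""
        volume = np.asarray(volume)
        if volume.shape != self.grid_shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match mask grid {self.grid_shape}"
            )
        return volume.ravel(order="C")[self._ravel_pos]

    def insert(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-V vector back into a 3-D volume (fill elsewhere)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels,):
            raise ValueError(f"expected {self.n_voxels} values, got {values.shape}")
        out = np.full(int(np.prod(self.grid_shape)), fill, dtype=float)
        out[self._ravel_pos] = values
        return out.reshape(self.grid_shape)


@dataclass
class Cohort:
    """Subject-by-voxel gray-matter density matrix with ages and group labels.

    ``X[i, j]`` is the (unitless) GM density of subject ``i`` at mask voxel
    ``j``; ``labels`` are +1 for young and -1 for old.
    """

    X: np.ndarray
    ages: np.ndarray
    labels: np.ndarray
    mask: BrainMask
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D subject-by-voxel matrix")
        n, v = self.X.shape
        if self.ages.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("ages and labels must each have one entry per subject")
        if not np.all(np.isin(self.labels, (1, -1))):
            raise ValueError("labels must be +1 (young) or -1 (old)")
        if v != self.mask.n_voxels:
            raise ValueError(
                f"X has {v} columns but the mask has {self.mask.n_voxels} voxels"
            )
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:04d}" for i in range(n)]

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "Cohort":
        """Cohort restricted to a subset of subjects."""
        rows = np.asarray(rows)
        return Cohort(
            X=self.X[rows],
            ages=self.ages[rows],
            labels=self.labels[rows],
            mask=self.mask,
            subject_ids=[self.subject_ids[i] for i in np.atleast_1d(rows)],
        )


def make_mask(volumes: np.ndarray | Sequence[np.ndarray], threshold: float = 0.1,
              affine: np.ndarray | None = None) -> BrainMask:
    """Build an analysis mask from a stack of density volumes.

    A voxel enters the mask iff its mean density across subjects exceeds
    ``threshold``.  This stands in for the implicit masking of VBM software;
    the default of 0.1 is a conventional GM-probability cutoff.
    """
    stack = np.asarray(volumes, dtype=float)
    if stack.ndim == 3:
        stack = stack[None]
    if stack.ndim != 4 or stack.shape[0] < 1:
        raise ValueError("expected at least one 3-D volume")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    in_mask = stack.mean(axis=0) > threshold
    if not in_mask.any():
        raise ValueError(f"no voxels survive the mask threshold {threshold}")
    if affine is None:
        affine = np.eye(4)
    return BrainMask(in_mask=in_mask, affine=affine)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a subject TSV with columns subject_id, age, group (young|old)."""
    table = pd.read_csv(path, sep="\t")
    missing = {"subject_id", "age", "group"} - set(table.columns)
    if missing:
        raise ValueError(f"subject table is missing columns: {sorted(missing)}")
    return table


def load_gm_maps(
    volume_paths: Sequence[str | Path],
    subject_table: pd.DataFrame,
    mask: BrainMask | None = None,
    mask_threshold: float = 0.1,
) -> Cohort:
    """Load per-subject GM density volumes into a :class:`Cohort`.

    ``subject_table`` rows correspond to ``volume_paths`` in order and must
    carry ``subject_id``, ``age`` and ``group`` (``young``/``old``) columns.
    If no mask is given one is built with :func:`make_mask`.
    """
    if len(volume_paths) != len(subject_table):
        raise ValueError("subject table length does not match number of volumes")
    bad = set(subject_table["group"]) - set(GROUP_CODES)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected 'young' or 'old'")

    volumes = []
    shape = None
    affine = None
    for p in volume_paths:
        img = nib.load(str(p))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 3:
            raise ValueError(f"{p}: expected a 3-D volume, got shape {data.shape}")
        if shape is None:
            shape, affine = data.shape, img.affine
        elif data.shape != shape:
            raise ValueError(f"{p}: volume shape {data.shape} does not match {shape}")
        volumes.append(data)
    stack = np.stack(volumes)

    if mask is None:
        mask = make_mask(stack, threshold=mask_threshold, affine=affine)
    elif mask.grid_shape != shape:
        raise ValueError(
            f"mask grid {mask.grid_shape} does not match volume shape {shape}"
        )

    X = np.stack([mask.extract(v) for v in volumes])
    return Cohort(
        X=X,
        ages=subject_table["age"].to_numpy(dtype=float),
        labels=np.array([GROUP_CODES[g] for g in subject_table["group"]]),
        mask=mask,
        subject_ids=[str(s) for s in subject_table["subject_id"]],
    )


def save_score_map(
    scores: Mapping[int, float] | tuple[np.ndarray, np.ndarray],
    mask: BrainMask,
    out_path: str | Path,
) -> Path:
    """Write per-voxel scores into a NIfTI volume.

    ``scores`` maps flat voxel indices to values (a dict, or an
    ``(indices, values)`` pair).  Out-of-mask and unscored voxels are 0.
    """
    if isinstance(scores, Mapping):
        idx = np.fromiter(scores.keys(), dtype=int, count=len(scores))
        vals = np.fromiter(scores.values(), dtype=float, count=len(scores))
    else:
        idx, vals = (np.asarray(a) for a in scores)
    full = np.zeros(mask.n_voxels)
    if idx.size:
        if idx.min() < 0 or idx.max() >= mask.n_voxels:
            raise IndexError("flat voxel index out of range for this mask")
        full[idx] = vals
    img = nib.Nifti1Image(mask.insert(full).astype(np.float32), mask.affine)
    out_path = Path(out_path)
    nib.save(img, str(out_path))
    return out_path


def load_score_map(path: str | Path, mask: BrainMask) -> np.ndarray:
    """Read a score map written by :func:`save_score_map` back to a vector."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return mask.extract(data)
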