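"""Coordinate conventions, label volumes and ROI registries.

All spatial stages share the conventions defined here:

* voxel indices are 0-based integer triples ``(i, j, k)``;
* a voxel ``v`` occupies the half-open box ``[v, v + 1)`` in continuous
  voxel space, so a continuous coordinate is assigned to a voxel by
  *flooring* each component (never rounding);
* an affine is a 4x4 matrix mapping homogeneous voxel coordinates to
  world millimetre coordinates, in the NIfTI convention;
* hemisphere membership is an attribute of a labelled structure
  (``left`` / ``right`` / ``midline``), never inferred from a midline
  x-coordinate test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "midline")


class AffineTransform:
    """Invertible 4x4 voxel-to-world transform.

    Parameters
    ----------
    matrix
        4x4 array; the upper 3x4 block maps voxel indices to world mm.

    Raises
    ------
    ValueError
        If the matrix is not 4x4 or is singular.
    """

    def __init__(self, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {matrix.shape}")
        if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        self.matrix = matrix
        self.inverse = np.linalg.inv(matrix)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    def voxel_to_world(self, voxel: Sequence[float]) -> np.ndarray:
        """Map a (possibly continuous) voxel coordinate to world mm."""
        v = np.asarray(voxel, dtype=float)
        return self.matrix[:3, :3] @ v + self.matrix[:3, 3]

    def voxel_center_world(self, voxel: Sequence[int]) -> np.ndarray:
        """World coordinate of the *center* of an integer voxel."""
        return self.voxel_to_world(np.asarray(voxel, dtype=float) + 0.5)

    def world_to_continuous(self, point: Sequence[float]) -> np.ndarray:
        """Map world mm to continuous voxel coordinates (no flooring)."""
        p = np.asarray(point, dtype=float)
        return self.inverse[:3, :3] @ p + self.inverse[:3, 3]

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, AffineTransform) and np.array_equal(
            self.matrix, other.matrix
        )


def world_to_voxel(
    affine: AffineTransform,
    point: Sequence[float],
    shape: Sequence[int],
) -> tuple[int, int, int] | None:
    """Assign a world-mm point to the voxel whose box contains it.

    Applies the inverse affine, floors each continuous coordinate and
    returns the 0-based index triple, or ``None`` when any index falls
    outside ``shape`` (the out-of-bounds signal).
    """
    cont = affine.world_to_continuous(point)
    idx = np.floor(cont).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        return None
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def world_to_voxel_table(
    affine: AffineTransform,
    points: np.ndarray,
    shape: Sequence[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`world_to_voxel` over an ``(n, 3)`` point array.

    Returns ``(indices, in_bounds)`` where ``indices`` is ``(n, 3)`` int
    (undefined where out of bounds) and ``in_bounds`` a boolean mask.
    """
    pts = np.asarray(points, dtype=float)
    cont = pts @ affine.inverse[:3, :3].T + affine.inverse[:3, 3]
    idx = np.floor(cont).astype(int)
    shape_arr = np.asarray(shape)
    in_bounds = np.all((idx >= 0) & (idx < shape_arr), axis=1)
    return idx, in_bounds


@dataclass(frozen=True)
class ROIEntry:
    label: int
    name: str
    hemisphere: str

    def __post_init__(self):
        if self.label <= 0:
            raise ValueError(f"ROI label must be positive, got {self.label}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )


@dataclass
class ROIRegistry:
    """Ordered roster of labelled structures with hemisphere tags.

    ``name`` here is the full unique name (e.g. ``hippocampus_left``);
    ``structure`` strips the hemisphere suffix so bilateral pairs can be
    matched across hemispheres.
    """

    entries: list[ROIEntry] = field(default_factory=list)

    def __post_init__(self):
        labels = [e.label for e in self.entries]
        names = [e.name for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels in registry")
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names in registry")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @staticmethod
    def structure_of(name: str) -> str:
        for suffix in ("_left", "_right"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return name

    def by_label(self, label: int) -> ROIEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(f"label {label} not in registry")

    def by_name(self, name: str) -> ROIEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(f"ROI {name!r} not in registry")

    def structure_entries(self, structure: str) -> list[ROIEntry]:
        """All entries of a structure (1 for midline, 2 for bilateral)."""
        found = [
            e for e in self.entries if self.structure_of(e.name) == structure
        ]
        if not found:
            raise KeyError(f"structure {structure!r} not in registry")
        return found

    def is_bilateral(self, structure: str) -> bool:
        hemis = {e.hemisphere for e in self.structure_entries(structure)}
        return hemis == {"left", "right"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.label, e.name, e.hemisphere) for e in self.entries],
            columns=["label", "name", "hemisphere"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ROIRegistry":
        df = pd.read_csv(path, sep="\t")
        return cls(
            [
                ROIEntry(int(r.label), str(r.name), str(r.hemisphere))
                for r in df.itertuples(index=False)
            ]
        )


class LabelVolume:
    """3D integer label lattice with an affine and an ROI registry.

    Label 0 is background.  Every nonzero label present in the lattice
    must appear in the registry.
    """

    def __init__(
        self,
        data: np.ndarray,
        affine: AffineTransform,
        registry: ROIRegistry,
    ):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if data.min() < 0:
            raise ValueError("labels must be nonnegative")
        present = set(np.unique(data).tolist()) - {0}
        known = {e.label for e in registry}
        missing = present - known
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from registry")
        self.data = data
        self.affine = affine
        self.registry = registry

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def roi_voxels(self, label: int) -> set[tuple[int, int, int]]:
        """Exactly the voxel index triples carrying ``label``.

        The label must be registered; an empty set is a valid answer for
        a registered label absent from the lattice.
        """
        self.registry.by_label(label)  # raises KeyError if unknown
        idx = np.argwhere(self.data == label)
        return {tuple(int(c) for c in row) for row in idx}

    def roi_mask(self, label: int) -> np.ndarray:
        self.registry.by_label(label)
        return self.data == label

    def write_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(
            self.data.astype(np.int16), self.affine.matrix
        )
        nib.save(img, str(path))

    @classmethod
    def read_nifti(
        cls, path: str | Path, registry: ROIRegistry
    ) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.int32)
        return cls(data, AffineTransform(img.affine), registry)


def roi_voxels(volume: LabelVolume, label: int) -> set[tuple[int, int, int]]:
    """Module-level alias for :meth:`LabelVolume.roi_voxels`."""
    return volume.roi_voxels(label)
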