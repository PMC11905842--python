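"""Grid/volume/label data model and NIfTI I/O.

Volumes are thin wrappers around a 3D :class:`numpy.ndarray` plus a
:class:`VoxelGrid` describing voxel size and axis orientation.  All
downstream stages require their inputs to share one grid (same dims,
spacing equal within 1e-6 mm); registration and resampling are assumed to
have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "ScalarVolume",
    "LabelVolume",
    "BinaryMask",
    "TissueMap",
    "LabelTable",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "reorient",
    "BACKGROUND",
    "CSF",
    "GREY",
    "WHITE",
]

# tissue-map codes
BACKGROUND, CSF, GREY, WHITE = 0, 1, 2, 3

SPACING_ATOL_MM = 1e-6


class GridMismatchError(ValueError):
    """Raised when two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice.

    Parameters
    ----------
    dims
        Number of voxels along each axis, all >= 1.
    spacing
        Voxel edge length in mm along each axis, all > 0.
    affine
        4x4 voxel-to-world matrix.  Defaults to a diagonal RAS affine
        built from ``spacing``; preserved through NIfTI round trips.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None, compare=False, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        if self.affine is None:
            aff = np.diag([*spacing, 1.0])
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be 4x4")
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValueError("degenerate affine")
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def compatible(self, other: "VoxelGrid") -> bool:
        return self.dims == other.dims and np.allclose(
            self.spacing, other.spacing, atol=SPACING_ATOL_MM, rtol=0.0
        )

    def require_compatible(self, other: "VoxelGrid") -> None:
        if not self.compatible(other):
            raise GridMismatchError(
                f"grids differ: dims {self.dims} vs {other.dims}, "
                f"spacing {self.spacing} vs {other.spacing}"
            )


def _check_shape(grid: VoxelGrid, data: np.ndarray) -> None:
    if tuple(data.shape) != grid.dims:
        raise ValueError(f"data shape {data.shape} does not match grid dims {grid.dims}")


@dataclass
class ScalarVolume:
    """Real-valued 3D image (T1, T2, bias field, logit sums, ...)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        _check_shape(self.grid, self.values)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar volume contains non-finite values")

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.grid, values)


@dataclass
class LabelVolume:
    """Integer-labeled 3D image; 0 means unlabeled/background."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("label data must be integer-valued")
            labels = labels.astype(np.int32)
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.labels = labels.astype(np.int32)
        _check_shape(self.grid, self.labels)

    def with_labels(self, labels: np.ndarray) -> "LabelVolume":
        return type(self)(self.grid, labels)

    def present_labels(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


class BinaryMask(LabelVolume):
    """LabelVolume restricted to {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.labels.max(initial=0) > 1:
            raise ValueError("binary mask may only contain 0 and 1")

    @property
    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


class TissueMap(LabelVolume):
    """LabelVolume with codes 0=background, 1=CSF, 2=grey, 3=white."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.labels.max(initial=0) > WHITE:
            raise ValueError("tissue map may only contain codes 0..3")


# ---------------------------------------------------------------------------
# Label table


_TISSUE_CLASSES = ("GM", "WM", "ventricle_CSF")
_HEMISPHERES = ("left", "right", "both")

LABEL_TABLE_COLUMNS = ["label", "name", "tissue_class", "hemisphere", "is_cerebellum", "is_cortical"]


class LabelTable:
    """Per-label metadata: name, tissue class, hemisphere, cerebellum/cortical flags.

    Backed by a :class:`pandas.DataFrame` with one row per positive label id.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = set(LABEL_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"label table missing columns {sorted(missing)}")
        df["label"] = df["label"].astype(int)
        df["is_cerebellum"] = df["is_cerebellum"].astype(bool)
        df["is_cortical"] = df["is_cortical"].astype(bool)
        if (df["label"] <= 0).any():
            raise ValueError("label ids must be positive")
        if df["label"].duplicated().any():
            raise ValueError("duplicate label ids")
        bad = ~df["tissue_class"].isin(_TISSUE_CLASSES)
        if bad.any():
            raise ValueError(f"unknown tissue_class values: {df.loc[bad, 'tissue_class'].unique()}")
        bad = ~df["hemisphere"].isin(_HEMISPHERES)
        if bad.any():
            raise ValueError(f"unknown hemisphere values: {df.loc[bad, 'hemisphere'].unique()}")
        self.df = df.set_index("label", drop=False).sort_index()

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "LabelTable":
        return cls(pd.DataFrame(list(rows)))

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabelTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    # -- queries ------------------------------------------------------------

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def __contains__(self, label: int) -> bool:
        return int(label) in self.df.index

    def covers(self, volume: LabelVolume) -> bool:
        return bool(np.isin(volume.present_labels(), self.labels).all())

    def require_covers(self, volume: LabelVolume) -> None:
        extra = np.setdiff1d(volume.present_labels(), self.labels)
        if extra.size:
            raise ValueError(f"labels {extra.tolist()} missing from label table")

    def _select(self, mask: pd.Series) -> np.ndarray:
        return self.df.loc[mask, "label"].to_numpy()

    def wm_labels(self, cerebellum: bool | None = None) -> np.ndarray:
        m = self.df["tissue_class"] == "WM"
        if cerebellum is not None:
            m &= self.df["is_cerebellum"] == cerebellum
        return self._select(m)

    def gm_labels(self, cerebellum: bool | None = None) -> np.ndarray:
        m = self.df["tissue_class"] == "GM"
        if cerebellum is not None:
            m &= self.df["is_cerebellum"] == cerebellum
        return self._select(m)

    def ventricle_labels(self) -> np.ndarray:
        return self._select(self.df["tissue_class"] == "ventricle_CSF")

    def cortical_labels(self) -> np.ndarray:
        return self._select(self.df["is_cortical"])

    def hemisphere_labels(self, side: str) -> np.ndarray:
        return self._select(self.df["hemisphere"] == side)

    def cerebellar_wm_label(self) -> int:
        ids = self.wm_labels(cerebellum=True)
        if len(ids) != 1:
            raise ValueError(f"expected exactly one cerebellar WM label, found {ids.tolist()}")
        return int(ids[0])

    def cerebellar_gm_label(self) -> int:
        ids = self.gm_labels(cerebellum=True)
        if len(ids) != 1:
            raise ValueError(f"expected exactly one cerebellar GM label, found {ids.tolist()}")
        return int(ids[0])

    def name_of(self, label: int) -> str:
        return str(self.df.at[int(label), "name"])

    def with_rows(self, rows: Iterable[dict]) -> "LabelTable":
        return LabelTable(pd.concat([self.df.reset_index(drop=True), pd.DataFrame(list(rows))],
                                    ignore_index=True))


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path, expect: str = "scalar") -> ScalarVolume | LabelVolume:
    """Read a single-file NIfTI image.

    ``expect`` selects the returned type: ``"scalar"`` yields a
    :class:`ScalarVolume`, ``"label"`` / ``"mask"`` / ``"tissue"`` yield the
    corresponding integer volume and reject non-integer voxel data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(tuple(data.shape), tuple(float(z) for z in zooms), np.asarray(img.affine))
    if expect == "scalar":
        return ScalarVolume(grid, data.astype(np.float32))
    if expect in ("label", "mask", "tissue"):
        if not np.all(data == np.round(data)):
            raise ValueError(f"{path}: non-integer data where labels were expected")
        cls = {"label": LabelVolume, "mask": BinaryMask, "tissue": TissueMap}[expect]
        return cls(grid, data.astype(np.int32))
    raise ValueError(f"expect must be 'scalar', 'label', 'mask' or 'tissue', got {expect!r}")


def write_volume(vol: ScalarVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI; scalars as float32, labels as int32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int32)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Reorientation


def _check_permutation(permutation: Sequence[int]) -> tuple[int, int, int]:
    perm = tuple(int(p) for p in permutation)
    if sorted(perm) != [0, 1, 2]:
        raise ValueError(f"permutation must be a bijection of {{0,1,2}}, got {permutation}")
    return perm  # type: ignore[return-value]


def reorient(vol, permutation: Sequence[int], flips: Sequence[bool]):
    """Swap and flip volume axes.

    Axis ``i`` of the output is axis ``permutation[i]`` of the input,
    reversed where ``flips[i]`` is set.  Grid dims and spacing are permuted
    consistently; the affine is updated so world coordinates of each voxel
    are preserved.
    """
    perm = _check_permutation(permutation)
    flips = tuple(bool(f) for f in flips)
    if len(flips) != 3:
        raise ValueError("flips must have length 3")
    data = vol.labels if isinstance(vol, LabelVolume) else vol.values
    out = np.transpose(data, perm)
    dims = tuple(vol.grid.dims[p] for p in perm)
    spacing = tuple(vol.grid.spacing[p] for p in perm)
    # voxel index map: old_index[perm[i]] = new_index[i] (or flipped)
    mat = np.zeros((4, 4))
    mat[3, 3] = 1.0
    for i, p in enumerate(perm):
        if flips[i]:
            mat[p, i] = -1.0
            mat[p, 3] = dims[i] - 1
        else:
            mat[p, i] = 1.0
    affine = vol.grid.affine @ mat
    for i in range(3):
        if flips[i]:
            out = np.flip(out, axis=i)
    grid = VoxelGrid(dims, spacing, affine)
    if isinstance(vol, LabelVolume):
        return type(vol)(grid, np.ascontiguousarray(out))
    return ScalarVolume(grid, np.ascontiguousarray(out))


def inverse_orientation(permutation: Sequence[int], flips: Sequence[bool]):
    """Return (perm, flips) undoing :func:`reorient` with the given arguments."""
    perm = _check_permutation(permutation)
    flips = tuple(bool(f) for f in flips)
    inv = tuple(perm.index(i) for i in range(3))
    inv_flips = tuple(flips[inv[i]] for i in range(3))
    return inv, inv_flips
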