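"""Training-patch sampling and patch extraction for the directional models.

Patches are 16x16 in-plane windows anchored by their minimal corner and
extracted simultaneously from the T1 and T2 volumes to form 2-channel
inputs; the target is the brain mask restricted to the same window.  The
three directions are named after the through-plane axis: ``sagittal``
(axis 0), ``coronal`` (axis 1), ``axial`` (axis 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..core import BinaryMask, ScalarVolume

__all__ = [
    "AXES",
    "PATCH",
    "PatchSet",
    "normalize_volume",
    "sample_training_patches",
    "inference_corners",
    "extract_patches",
    "loo_training_patch_count",
]

PATCH = 16
AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class PatchSet:
    """Aligned 2-channel input patches and binary target patches."""

    axis: str
    inputs: np.ndarray   # (N, 2, 16, 16)
    targets: np.ndarray  # (N, 16, 16)
    corners: np.ndarray  # (N, 3) minimal-corner voxel indices

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {sorted(AXES)}, got {self.axis!r}")
        if len(self.inputs) != len(self.targets) or len(self.inputs) != len(self.corners):
            raise ValueError("inputs, targets and corners must align one-to-one")

    def __len__(self) -> int:
        return len(self.inputs)


def normalize_volume(values: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0) -> np.ndarray:
    """Rescale so the (p_lo, p_hi) intensity percentiles map to (0, 1).

    The same rule is applied to training and inference volumes; raw scanner
    units are arbitrary and the formalin T2 brights make min/max scaling
    unstable, so robust percentiles are used instead.
    """
    lo, hi = np.percentile(values, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(values, dtype=float)
    return (values.astype(float) - lo) / (hi - lo)


def _inplane_axes(axis: str) -> tuple[int, int]:
    k = AXES[axis]
    return tuple(a for a in range(3) if a != k)  # type: ignore[return-value]


def extract_patches(values: np.ndarray, axis: str, corners: np.ndarray) -> np.ndarray:
    """Gather 16x16 in-plane windows at the given minimal corners."""
    i, j = _inplane_axes(axis)
    win = sliding_window_view(values, (PATCH, PATCH), axis=(i, j))
    return win[corners[:, 0], corners[:, 1], corners[:, 2]]


def sample_training_patches(
    pair: tuple[ScalarVolume, ScalarVolume],
    mask: BinaryMask,
    axis: str,
    n: int,
    seed: int | np.random.Generator = 0,
    normalized: bool = False,
) -> PatchSet:
    """Draw ``n`` patches at uniformly random in-bounds positions.

    ``normalized=True`` skips the percentile rescale (for volumes already
    normalized by the caller).
    """
    t1, t2 = pair
    t1.grid.require_compatible(t2.grid)
    t1.grid.require_compatible(mask.grid)
    dims = t1.grid.dims
    i, j = _inplane_axes(axis)
    if dims[i] < PATCH or dims[j] < PATCH:
        raise ValueError(f"in-plane dims {dims[i]}x{dims[j]} smaller than patch size {PATCH}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    corners = np.zeros((n, 3), dtype=int)
    k = AXES[axis]
    corners[:, k] = rng.integers(0, dims[k], size=n)
    corners[:, i] = rng.integers(0, dims[i] - PATCH + 1, size=n)
    corners[:, j] = rng.integers(0, dims[j] - PATCH + 1, size=n)

    v1 = t1.values if normalized else normalize_volume(t1.values)
    v2 = t2.values if normalized else normalize_volume(t2.values)
    if n == 0:
        return PatchSet(axis, np.zeros((0, 2, PATCH, PATCH)), np.zeros((0, PATCH, PATCH)),
                        corners)
    inputs = np.stack([extract_patches(v1, axis, corners),
                       extract_patches(v2, axis, corners)], axis=1)
    targets = extract_patches(mask.labels.astype(float), axis, corners)
    return PatchSet(axis, inputs, targets, corners)


def inference_corners(dims: tuple[int, int, int], axis: str, stride: int = 5) -> np.ndarray:
    """Tiling grid: every through-plane position, stride grid in-plane.

    The final valid in-plane position is appended when the stride grid does
    not already reach it, so coverage is complete up to the border.
    """
    k = AXES[axis]
    i, j = _inplane_axes(axis)

    def grid_1d(d: int) -> np.ndarray:
        pos = list(range(0, d - PATCH + 1, stride))
        if pos[-1] != d - PATCH:
            pos.append(d - PATCH)
        return np.array(pos)

    through = np.arange(dims[k])
    gi, gj = grid_1d(dims[i]), grid_1d(dims[j])
    tt, ii, jj = np.meshgrid(through, gi, gj, indexing="ij")
    corners = np.zeros((tt.size, 3), dtype=int)
    corners[:, k] = tt.ravel()
    corners[:, i] = ii.ravel()
    corners[:, j] = jj.ravel()
    return corners


def loo_training_patch_count(n_scans: int, patches_per_scan: int) -> int:
    """Patches each directional model sees in one leave-one-out fold."""
    return (n_scans - 1) * patches_per_scan
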