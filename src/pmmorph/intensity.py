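"""Intensity correction and cross-scan intensity matching.

Two independent tools live here.  ``correct_intensity`` removes residual
low-spatial-frequency signal inside a brain mask by normalized
convolution: the masked image and the mask are smoothed with the same
Gaussian kernel (default 2 mm standard deviation), their ratio is a
border-safe estimate of the slowly varying gain field, and dividing the
original image by that field flattens it without altering grey/white
contrast at tissue borders; a final scalar rescale restores the original
mean over the mask.  ``match_intensity`` builds a monotone piecewise-linear
intensity mapping between two co-registered scans from co-located samples
(sorted source samples grouped into batches of 29, each batch contributing
one control point at the batch's target median), used to align several
differently calibrated scans of one session before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, ScalarVolume

__all__ = [
    "CorrectionConfig",
    "IntensityMapping",
    "correct_intensity",
    "match_intensity",
    "combine_session",
]


@dataclass(frozen=True)
class CorrectionConfig:
    sigma_mm: float = 2.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0 or self.epsilon <= 0:
            raise ValueError("sigma_mm and epsilon must be positive")


@dataclass(frozen=True)
class IntensityMapping:
    """Monotone piecewise-linear map; clamped beyond the end control points."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        src = np.asarray(self.source, dtype=float)
        tgt = np.asarray(self.target, dtype=float)
        if src.ndim != 1 or src.shape != tgt.shape or src.size == 0:
            raise ValueError("control points must be two equal-length 1D arrays")
        if np.any(np.diff(src) <= 0):
            raise ValueError("source abscissae must be strictly increasing")
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "target", tgt)

    def apply(self, vol: ScalarVolume) -> ScalarVolume:
        mapped = np.interp(vol.values, self.source, self.target)
        return ScalarVolume(vol.grid, mapped)

    def __len__(self) -> int:
        return len(self.source)


def correct_intensity(vol: ScalarVolume, mask: BinaryMask,
                      config: CorrectionConfig | None = None) -> ScalarVolume:
    """Flatten low-frequency gain inside ``mask``; zero outside.

    The mean intensity over the mask is preserved exactly (up to float
    round-off) by the final rescale.
    """
    config = config or CorrectionConfig()
    vol.grid.require_compatible(mask.grid)
    m = mask.as_bool
    if not m.any():
        raise ValueError("empty mask")
    v = vol.values.astype(float)
    sigma_vox = [config.sigma_mm / s for s in vol.grid.spacing]
    smooth_masked = ndimage.gaussian_filter(v * m, sigma_vox, truncate=4.0)
    smooth_mask = ndimage.gaussian_filter(m.astype(float), sigma_vox, truncate=4.0)
    field = smooth_masked / np.maximum(smooth_mask, config.epsilon)
    corrected = np.where(m, v / np.maximum(field, config.epsilon), 0.0)
    mean_before = v[m].mean()
    mean_after = corrected[m].mean()
    if mean_after != 0:
        corrected *= mean_before / mean_after
    return ScalarVolume(vol.grid, corrected)


def match_intensity(source: ScalarVolume, target: ScalarVolume,
                    n_samples: int = 100_000, batch: int = 29,
                    seed: int = 0,
                    mask: BinaryMask | None = None) -> IntensityMapping:
    """Estimate a monotone intensity mapping source -> target.

    ``n_samples`` voxel locations are drawn uniformly (within ``mask`` when
    given); the source samples are sorted and cut into consecutive batches
    of ``batch`` values (a trailing partial batch is dropped).  Each batch
    contributes one control point: the median of its co-located target
    samples as the ordinate, and as the abscissa the source value of the
    sample pair whose target value is closest to that median.  Target
    ordinates are made non-decreasing by cumulative maximum so the mapping
    is monotone.
    """
    source.grid.require_compatible(target.grid)
    if n_samples < batch:
        raise ValueError(f"n_samples ({n_samples}) must be >= batch size ({batch})")
    rng = np.random.default_rng(seed)
    src_vals = source.values.ravel()
    tgt_vals = target.values.ravel()
    if mask is not None:
        source.grid.require_compatible(mask.grid)
        pool = np.flatnonzero(mask.labels.ravel())
    else:
        pool = None
    if pool is not None:
        idx = pool[rng.integers(0, len(pool), size=n_samples)]
    else:
        idx = rng.integers(0, src_vals.size, size=n_samples)
    s = src_vals[idx].astype(float)
    t = tgt_vals[idx].astype(float)

    if np.ptp(s) == 0:
        warnings.warn("constant source volume: degenerate single-point mapping",
                      stacklevel=2)
        return IntensityMapping(np.array([s[0]]), np.array([np.median(t)]))

    order = np.argsort(s, kind="stable")
    s, t = s[order], t[order]
    n_batches = n_samples // batch
    s = s[: n_batches * batch].reshape(n_batches, batch)
    t = t[: n_batches * batch].reshape(n_batches, batch)

    medians = np.median(t, axis=1)
    closest = np.argmin(np.abs(t - medians[:, None]), axis=1)
    ctrl_src = s[np.arange(n_batches), closest]
    ctrl_tgt = medians

    # strictly increasing abscissae after deduplication
    order = np.argsort(ctrl_src, kind="stable")
    ctrl_src, ctrl_tgt = ctrl_src[order], ctrl_tgt[order]
    uniq, inverse = np.unique(ctrl_src, return_inverse=True)
    tgt_dedup = np.full(len(uniq), -np.inf)
    np.maximum.at(tgt_dedup, inverse, ctrl_tgt)
    # enforce monotone ordinates
    tgt_mono = np.maximum.accumulate(tgt_dedup)
    return IntensityMapping(uniq, tgt_mono)


def combine_session(volumes: list[ScalarVolume], seed: int = 0,
                    n_samples: int = 100_000, batch: int = 29) -> ScalarVolume:
    """Average a session's scans after matching each to the first.

    The first scan is the intensity reference, so the result depends on
    the input order (matching the convention of registering every scan of
    a session to the first one).
    """
    if not volumes:
        raise ValueError("combine_session needs at least one volume")
    ref = volumes[0]
    acc = ref.values.astype(float).copy()
    for k, vol in enumerate(volumes[1:], start=1):
        ref.grid.require_compatible(vol.grid)
        mapping = match_intensity(vol, ref, n_samples=n_samples, batch=batch,
                                  seed=seed + k)
        acc += mapping.apply(vol).values
    return ScalarVolume(ref.grid, acc / len(volumes))
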