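"""Training, tiled inference, mask cleanup, metrics and cross-validation.

Three directional autoencoders (sagittal, coronal, axial) are trained on
2-channel patches with a binary cross-entropy-from-logits loss under a
staged learning-rate schedule.  At inference, patches are tiled at every
through-plane position and on a stride grid in-plane; logits from all
overlapping patches of all three models are summed per voxel and the raw
mask keeps voxels with a strictly positive sum.  The cleanup fills holes
and keeps the largest connected component — a single hemisphere is one
connected object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..core import BinaryMask, ScalarVolume
from .model import PatchAutoencoderSpec, build_autoencoder
from .nnet import Adam, Sequential, bce_with_logits, bce_with_logits_grad
from .patches import AXES, PATCH, PatchSet, extract_patches, inference_corners, normalize_volume

__all__ = [
    "TrainConfig",
    "ModelTriplet",
    "SegMetrics",
    "train_triplet",
    "infer_logits",
    "infer_mask",
    "clean_mask",
    "evaluate_mask",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The defaults are the full schedule used on real scans: Adam
    (beta1=0.9, beta2=0.999, amsgrad), batch 250, and 25 epochs at each of
    five decreasing learning rates (125 epochs total).  Reduced schedules
    pass shorter ``learning_rates``/``epochs_per_rate``.
    """

    batch_size: int = 250
    learning_rates: tuple[float, ...] = (0.02, 0.01, 0.005, 0.002, 0.001)
    epochs_per_rate: int = 25
    beta1: float = 0.9
    beta2: float = 0.999
    amsgrad: bool = True
    patches_per_scan_per_axis: int = 25_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.learning_rates, self.learning_rates[1:])):
            raise ValueError("learning rates must be strictly decreasing")
        if self.batch_size < 1 or self.epochs_per_rate < 1:
            raise ValueError("batch size and epochs must be positive")

    @property
    def total_epochs(self) -> int:
        return len(self.learning_rates) * self.epochs_per_rate


@dataclass
class ModelTriplet:
    """One trained model per direction plus the normalization convention."""

    models: dict[str, Sequential]
    spec: PatchAutoencoderSpec
    config: TrainConfig
    norm_percentiles: tuple[float, float] = (1.0, 99.0)
    history: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.models) != set(AXES):
            raise ValueError(f"expected one model per axis {sorted(AXES)}")


def _train_one(patches: PatchSet, config: TrainConfig, spec: PatchAutoencoderSpec,
               seed: int) -> tuple[Sequential, list[float]]:
    if len(patches) == 0:
        raise ValueError(f"empty patch set for axis {patches.axis}")
    rng = np.random.default_rng(seed)
    model = build_autoencoder(spec, rng)
    x = patches.inputs.astype(np.float32)
    y = patches.targets.astype(np.float32)[:, None]  # (N,1,16,16)
    n = len(x)
    losses: list[float] = []
    opt = Adam(model, lr=config.learning_rates[0], beta1=config.beta1,
               beta2=config.beta2, amsgrad=config.amsgrad)
    for lr in config.learning_rates:
        opt.lr = lr
        for _ in range(config.epochs_per_rate):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                sel = order[start:start + config.batch_size]
                xb, yb = x[sel], y[sel]
                logits = model.forward(xb, training=True, rng=rng)
                loss = bce_with_logits(logits, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss on axis {patches.axis} (lr={lr})")
                model.backward(bce_with_logits_grad(logits, yb))
                opt.step()
                epoch_loss += loss * len(sel)
            losses.append(epoch_loss / n)
    return model, losses


def train_triplet(patch_sets: dict[str, PatchSet] | list[PatchSet],
                  config: TrainConfig | None = None,
                  spec: PatchAutoencoderSpec | None = None) -> ModelTriplet:
    """Train the three directional models on their patch sets."""
    config = config or TrainConfig()
    spec = spec or PatchAutoencoderSpec()
    if not isinstance(patch_sets, dict):
        patch_sets = {ps.axis: ps for ps in patch_sets}
    if set(patch_sets) != set(AXES):
        raise ValueError(f"need one patch set per axis {sorted(AXES)}")
    models: dict[str, Sequential] = {}
    history: dict[str, list[float]] = {}
    for i, axis in enumerate(sorted(AXES)):
        models[axis], history[axis] = _train_one(
            patch_sets[axis], config, spec, seed=config.seed * 31 + i)
    return ModelTriplet(models=models, spec=spec, config=config, history=history)


def _forward_chunks(model: Sequential, x: np.ndarray, chunk: int = 1024) -> np.ndarray:
    outs = [model.forward(x[i:i + chunk], training=False)
            for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)


def infer_logits(triplet: ModelTriplet, pair: tuple[ScalarVolume, ScalarVolume],
                 axis: str, stride: int = 5) -> ScalarVolume:
    """Per-voxel sum of logits contributed by one directional model."""
    t1, t2 = pair
    t1.grid.require_compatible(t2.grid)
    dims = t1.grid.dims
    if min(dims) < PATCH:
        raise ValueError(f"every dimension must be >= {PATCH}, got {dims}")
    p_lo, p_hi = triplet.norm_percentiles
    v1 = normalize_volume(t1.values, p_lo, p_hi)
    v2 = normalize_volume(t2.values, p_lo, p_hi)
    corners = inference_corners(dims, axis, stride)
    x = np.stack([extract_patches(v1, axis, corners),
                  extract_patches(v2, axis, corners)], axis=1).astype(np.float32)
    logits = _forward_chunks(triplet.models[axis], x)[:, 0].astype(float)  # (N,16,16)
    acc = np.zeros(dims, dtype=float)
    i, j = [a for a in range(3) if a != AXES[axis]]
    k = AXES[axis]
    for patch, corner in zip(logits, corners):
        sl = [None, None, None]
        sl[k] = slice(corner[k], corner[k] + 1)
        sl[i] = slice(corner[i], corner[i] + PATCH)
        sl[j] = slice(corner[j], corner[j] + PATCH)
        block = acc[tuple(sl)]
        # orient the 2D patch into the 3D slab: in-plane axes keep their order
        shape = [1, 1, 1]
        shape[i], shape[j] = PATCH, PATCH
        block += patch.reshape(shape)
    return ScalarVolume(t1.grid, acc)


def infer_mask(triplet: ModelTriplet, pair: tuple[ScalarVolume, ScalarVolume],
               stride: int = 5) -> tuple[ScalarVolume, BinaryMask]:
    """Fuse the three directional models by summing their logit volumes.

    Returns the summed logit volume and the raw mask of voxels with a
    strictly positive sum.
    """
    total = None
    for axis in sorted(AXES):
        vol = infer_logits(triplet, pair, axis, stride)
        total = vol.values if total is None else total + vol.values
    logit_sum = ScalarVolume(pair[0].grid, total)
    raw = BinaryMask(pair[0].grid, (total > 0).astype(np.int32))
    return logit_sum, raw


def clean_mask(raw: BinaryMask, min_component_fraction: float = 0.05) -> BinaryMask:
    """Fill holes, then drop small disconnected 26-connected clusters.

    Hole filling uses 6-connectivity for the background; component pruning
    uses 26-connectivity for the foreground.  Components smaller than
    ``min_component_fraction`` of the largest one are removed — spurious
    specks go, but genuinely separate structures survive: in a postmortem
    sample the cerebellum floats detached from the forebrain and must not
    be discarded as a "disconnected cluster".  Idempotent; an empty mask
    is returned empty.
    """
    fg = raw.as_bool
    if not fg.any():
        import warnings

        warnings.warn("clean_mask: empty input mask", stacklevel=2)
        return BinaryMask(raw.grid, np.zeros_like(raw.labels))
    filled = ndimage.binary_fill_holes(fg)  # default structure = 6-connectivity
    labeled, n = ndimage.label(filled, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = np.bincount(labeled.ravel())[1:]
        keep = 1 + np.flatnonzero(sizes >= min_component_fraction * sizes.max())
        filled = np.isin(labeled, keep)
    return BinaryMask(raw.grid, filled.astype(np.int32))


@dataclass(frozen=True)
class SegMetrics:
    """Confusion counts and the Dice / TPR / TNR ratios derived from them."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def dice(self) -> float:
        denom = 2 * self.TP + self.FP + self.FN
        return 2 * self.TP / denom if denom else 1.0

    @property
    def tpr(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else 1.0

    @property
    def tnr(self) -> float:
        denom = self.TN + self.FP
        return self.TN / denom if denom else 1.0

    def as_dict(self) -> dict[str, float]:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
                "dice": self.dice, "tpr": self.tpr, "tnr": self.tnr}

    def __add__(self, other: "SegMetrics") -> "SegMetrics":
        return SegMetrics(self.TP + other.TP, self.TN + other.TN,
                          self.FP + other.FP, self.FN + other.FN)


def evaluate_mask(pred: BinaryMask, truth: BinaryMask) -> SegMetrics:
    pred.grid.require_compatible(truth.grid)
    p, t = pred.as_bool, truth.as_bool
    return SegMetrics(
        TP=int(np.count_nonzero(p & t)),
        TN=int(np.count_nonzero(~p & ~t)),
        FP=int(np.count_nonzero(p & ~t)),
        FN=int(np.count_nonzero(~p & t)),
    )


def cross_validate(
    samples: list[tuple[tuple[ScalarVolume, ScalarVolume], BinaryMask]],
    config: TrainConfig | None = None,
    n_test_per_fold: int = 1,
    stride: int = 5,
) -> dict:
    """Grouped leave-out cross-validation of the full extract/train/infer loop.

    With ``n_test_per_fold=1`` this is leave-one-out: for each held-out
    sample a triplet is trained on all the others and evaluated on the
    held-out pair after inference and cleanup.  Larger groups hold out
    consecutive blocks.  Returns per-fold metrics, their arithmetic mean,
    and pulled metrics computed from confusion counts summed across folds.
    """
    from .patches import sample_training_patches

    config = config or TrainConfig()
    n = len(samples)
    if n < 2:
        raise ValueError("cross-validation needs at least 2 samples")
    if n % n_test_per_fold != 0:
        raise ValueError("n_test_per_fold must divide the number of samples")

    per_sample: list[SegMetrics] = []
    fold_of: list[int] = []
    for fold_start in range(0, n, n_test_per_fold):
        test_idx = set(range(fold_start, fold_start + n_test_per_fold))
        patch_sets = {}
        for ai, axis in enumerate(sorted(AXES)):
            parts = []
            for si, (pair, mask) in enumerate(samples):
                if si in test_idx:
                    continue
                seed = (config.seed * 1009 + fold_start * 97 + si * 13 + ai) % (2**31)
                parts.append(sample_training_patches(
                    pair, mask, axis, config.patches_per_scan_per_axis, seed=seed))
            if not parts:
                raise ValueError("a fold has no training samples")
            patch_sets[axis] = PatchSet(
                axis,
                np.concatenate([p.inputs for p in parts]),
                np.concatenate([p.targets for p in parts]),
                np.concatenate([p.corners for p in parts]),
            )
        triplet = train_triplet(patch_sets, config)
        for si in sorted(test_idx):
            pair, truth = samples[si]
            _, raw = infer_mask(triplet, pair, stride=stride)
            per_sample.append(evaluate_mask(clean_mask(raw), truth))
            fold_of.append(fold_start // n_test_per_fold)

    pulled = per_sample[0]
    for m in per_sample[1:]:
        pulled = pulled + m
    average = {
        "dice": float(np.mean([m.dice for m in per_sample])),
        "tpr": float(np.mean([m.tpr for m in per_sample])),
        "tnr": float(np.mean([m.tnr for m in per_sample])),
    }
    return {"per_sample": per_sample, "fold_of": fold_of,
            "average": average, "pulled": pulled}
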