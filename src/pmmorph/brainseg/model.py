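"""The dual-modality patch autoencoder used for postmortem brain extraction.

A compact encoder/decoder that maps a 2-channel (T1, T2) 16x16 patch to a
16x16 logit patch.  The encoder is three 12-kernel 5x5 convolutional
layers (each followed by batch normalization and a leaky ReLU with slope
0.1); spatial maps shrink 16 -> 8 -> 4 -> 4 so that flattening yields 192
features.  A 192->192 dense bottleneck with dropout 0.25 feeds a mirrored
decoder of two 12-kernel transposed-convolution layers and a final
single-kernel transposed convolution emitting raw logits (no batch norm,
no activation).  The full model has 52,657 parameters: 52,537 trainable
and 120 non-trainable batch-norm running statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import (
    BatchNorm2D,
    Conv2D,
    ConvTranspose2D,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    Reshape,
    Sequential,
)

__all__ = ["PatchAutoencoderSpec", "build_autoencoder", "count_parameters"]


@dataclass(frozen=True)
class PatchAutoencoderSpec:
    """Architecture constants of the directional patch models.

    The defaults are the model actually used for brain extraction; the
    encoder strides (2, 2, 1) are the unique plan under 'same' padding that
    shrinks a 16x16 patch to the 4x4x12 map whose flattening has exactly
    192 features, and the decoder mirrors them as (1, 2, 2).
    """

    patch_size: int = 16
    in_channels: int = 2
    n_kernels: int = 12
    kernel_size: int = 5
    leaky_slope: float = 0.1
    bottleneck: int = 192
    dropout_rate: float = 0.25
    encoder_strides: tuple[int, int, int] = (2, 2, 1)
    decoder_strides: tuple[int, int, int] = (1, 2, 2)

    def encoder_output_hw(self) -> int:
        size = self.patch_size
        for s in self.encoder_strides:
            size = -(-size // s)  # ceil division ('same' padding)
        return size

    def __post_init__(self) -> None:
        flat = self.encoder_output_hw() ** 2 * self.n_kernels
        if flat != self.bottleneck:
            raise ValueError(
                f"encoder flatten size {flat} != bottleneck {self.bottleneck}; "
                "strides/kernel counts inconsistent with the 192-feature plan"
            )
        out = self.encoder_output_hw()
        for s in self.decoder_strides:
            out *= s
        if out != self.patch_size:
            raise ValueError("decoder strides do not restore the patch size")


def build_autoencoder(spec: PatchAutoencoderSpec | None = None,
                      rng: np.random.Generator | int | None = None) -> Sequential:
    """Build an untrained patch autoencoder per ``spec``.

    The forward pass maps a (N, 2, 16, 16) batch to (N, 1, 16, 16) logits.
    """
    spec = spec or PatchAutoencoderSpec()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    k, nk, a = spec.kernel_size, spec.n_kernels, spec.leaky_slope
    layers = []
    hw = spec.patch_size
    in_ch = spec.in_channels
    for stride in spec.encoder_strides:
        layers += [
            Conv2D(in_ch, nk, k, stride, (hw, hw), rng),
            BatchNorm2D(nk),
            LeakyReLU(a),
        ]
        hw = -(-hw // stride)
        in_ch = nk
    layers += [
        Flatten(),
        Dense(hw * hw * nk, spec.bottleneck, rng),
        Dropout(spec.dropout_rate),
        Reshape((nk, hw, hw)),
    ]
    *body_strides, last_stride = spec.decoder_strides
    for stride in body_strides:
        layers += [
            ConvTranspose2D(nk, nk, k, stride, (hw, hw), rng),
            BatchNorm2D(nk),
            LeakyReLU(a),
        ]
        hw *= stride
    # final layer: one kernel, no batch norm, no activation -> logits
    layers.append(ConvTranspose2D(nk, 1, k, last_stride, (hw, hw), rng))
    return Sequential(layers)


def count_parameters(model: Sequential) -> tuple[int, int, int]:
    """Return (total, trainable, non_trainable) parameter counts.

    Trainable: convolution/dense weights and biases plus batch-norm
    scale/shift.  Non-trainable: batch-norm running mean/variance.
    """
    trainable = model.n_trainable()
    non_trainable = model.n_non_trainable()
    return trainable + non_trainable, trainable, non_trainable
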