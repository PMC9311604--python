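"""The per-branch EEGNet feature extractor.

Three convolution stages, as in the compact EEGNet lineage:

1. ``F1`` temporal filters of size 1 x K (same padding, no bias) + batch norm;
2. depthwise spatial convolution of size E x 1 with depth multiplier D
   (collapses the electrode axis) + batch norm, ELU, average pool 1 x pool1,
   dropout;
3. separable convolution (depthwise 1 x separable_kernel then pointwise to
   F2 = F1 * D channels) + batch norm, ELU, average pool 1 x pool2, dropout.

With the defaults (D = 2, pool1 = pool2 = 8, separable kernel 16) a
1125-sample trial becomes an F2 x 1 x 17 feature map regardless of the
electrode count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionConfig
from . import nn

__all__ = ["BranchConfig", "default_branch_configs", "EEGNetBlock",
           "eegnet_block_forward", "block_output_shape"]


@dataclass(frozen=True)
class BranchConfig:
    """Hyperparameters of one branch (EEGNet block + its attention block)."""

    n_temporal_filters: int
    temporal_kernel: int
    dropout_rate: float
    attention: AttentionConfig
    depth_multiplier: int = 2
    pool1: int = 8
    pool2: int = 8
    separable_kernel: int = 16

    def __post_init__(self):
        if min(self.n_temporal_filters, self.temporal_kernel, self.depth_multiplier,
               self.pool1, self.pool2, self.separable_kernel) < 1:
            raise ValueError("all size hyperparameters must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def n_output_channels(self) -> int:
        return self.n_temporal_filters * self.depth_multiplier


def default_branch_configs() -> tuple[BranchConfig, BranchConfig, BranchConfig]:
    """The three published branch settings.

    Temporal filters 4/8/16 with kernels 16/32/64 samples and dropout
    0/0.1/0.2; attention reduction ratios 2/8/8 with spatial kernels 2/4/2.
    """
    return (
        BranchConfig(4, 16, 0.0, AttentionConfig(ratio=2, kernel=2)),
        BranchConfig(8, 32, 0.1, AttentionConfig(ratio=8, kernel=4)),
        BranchConfig(16, 64, 0.2, AttentionConfig(ratio=8, kernel=2)),
    )


def block_output_shape(cfg: BranchConfig, input_shape: tuple[int, int]) -> tuple[int, int, int]:
    """Analytic output shape (F1*D, 1, floor(floor(T/pool1)/pool2)).

    The electrode count never enters the output shape (the depthwise spatial
    convolution collapses that axis); it must still be positive.
    """
    n_electrodes, n_samples = input_shape
    if n_electrodes < 1 or n_samples < 1:
        raise ValueError("input shape must be positive")
    t1 = n_samples // cfg.pool1
    if t1 < 1:
        raise ValueError(
            f"time axis of length {n_samples} too short for stage-2 pooling "
            f"(pool size {cfg.pool1})")
    t2 = t1 // cfg.pool2
    if t2 < 1:
        raise ValueError(
            f"time axis of length {t1} too short for stage-3 pooling "
            f"(pool size {cfg.pool2})")
    return (cfg.n_output_channels, 1, t2)


class EEGNetBlock(nn.Layer):
    """Parameterized three-stage feature extractor for one branch."""

    def __init__(self, cfg: BranchConfig, n_electrodes: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "eegnet"):
        self.cfg = cfg
        self.n_electrodes = int(n_electrodes)
        f1, d = cfg.n_temporal_filters, cfg.depth_multiplier
        f2 = cfg.n_output_channels
        self.layers: list[nn.Layer] = [
            nn.TemporalConv(f1, cfg.temporal_kernel, rng, dtype, f"{name}.conv1",
                            input_layer=True),
            nn.BatchNorm(f1, dtype=dtype, name=f"{name}.bn1"),
            nn.DepthwiseSpatialConv(f1, d, n_electrodes, rng, dtype, f"{name}.depthwise"),
            nn.BatchNorm(f2, dtype=dtype, name=f"{name}.bn2"),
            nn.ELU(),
            nn.AvgPool(cfg.pool1, stage="stage-2 pooling"),
            nn.Dropout(cfg.dropout_rate),
            nn.DepthwiseTemporalConv(f2, cfg.separable_kernel, rng, dtype,
                                     f"{name}.separable_depthwise"),
            nn.PointwiseConv(f2, f2, rng, dtype, f"{name}.separable_pointwise"),
            nn.BatchNorm(f2, dtype=dtype, name=f"{name}.bn3"),
            nn.ELU(),
            nn.AvgPool(cfg.pool2, stage="stage-3 pooling"),
            nn.Dropout(cfg.dropout_rate),
        ]

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def output_shape(self, input_shape: tuple[int, int]) -> tuple[int, int, int]:
        return block_output_shape(self.cfg, input_shape)

    def forward(self, x, training=False, rng=None):
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != self.n_electrodes:
            raise ValueError(
                f"expected input (N, 1, {self.n_electrodes}, T), got {x.shape}")
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def eegnet_block_forward(trial: np.ndarray, block: EEGNetBlock) -> np.ndarray:
    """Inference-mode forward of a single (E, T) trial -> (F2, 1, T'') map."""
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValueError(f"trial must be (electrodes, samples), got {trial.shape}")
    return block.forward(trial[None, None].astype(np.float32, copy=False))[0]
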