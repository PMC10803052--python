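"""MLP cross-gating block (MCG).

Two convolutional feature streams gate each other: each stream is
layer-normalized, projected and GELU-activated, passed through a shared
multi-axis multi-window MLP (:class:`~cgmunet.msm.MsMBlock`), and the MsM
output of *the other* stream multiplies it elementwise.  Each gated stream is
projected back, dropped out and added residually to its raw input; the block
returns the sum of the two streams.

With the output projections zeroed the block reduces exactly to ``u1 + v1``,
so the gating path is a learned perturbation of a plain additive fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DimensionError
from .msm import MsMBlock, MsMConfig
from .nn import Dense, Dropout, LayerNorm, Module, Tensor

__all__ = ["MCGConfig", "MCGBlock", "mcg_parameter_count"]


@dataclass(frozen=True)
class MCGConfig:
    """Channel width and MsM hyperparameters of one cross-gating block."""

    channels: int
    msm: MsMConfig = None  # type: ignore[assignment]
    dropout_rate: float = 0.1

    def __post_init__(self):
        if self.msm is None:
            object.__setattr__(self, "msm", MsMConfig(
                channels=self.channels, dropout_rate=self.dropout_rate))
        if self.msm.channels != self.channels:
            raise ConfigError(
                f"msm.channels ({self.msm.channels}) must equal channels "
                f"({self.channels})")
        if self.channels % 4:
            raise ConfigError(f"channels must be divisible by 4, got "
                              f"{self.channels}")


class MCGBlock(Module):
    """Cross-gated fusion of two equally shaped feature maps.

    The two streams have independent normalization and projection weights;
    the MsM operator is shared between them (a single spatial-mixing
    operator applied to both).
    """

    def __init__(self, cfg: MCGConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.norm_u = LayerNorm(c, dtype=dtype)
        self.proj_u = Dense(c, c, rng, dtype)
        self.norm_v = LayerNorm(c, dtype=dtype)
        self.proj_v = Dense(c, c, rng, dtype)
        self.msm = MsMBlock(cfg.msm, rng, dtype)
        self.out_u = Dense(c, c, rng, dtype)
        self.out_v = Dense(c, c, rng, dtype)
        self.drop_u = Dropout(cfg.dropout_rate, rng)
        self.drop_v = Dropout(cfg.dropout_rate, rng)

    def __call__(self, u1: Tensor, v1: Tensor) -> Tensor:
        if u1.shape != v1.shape:
            raise DimensionError(
                f"cross-gating inputs must share a shape, got {u1.shape} vs "
                f"{v1.shape}")
        u2 = self.proj_u(self.norm_u(u1)).gelu()
        v2 = self.proj_v(self.norm_v(v1)).gelu()
        mu = self.msm(u2)
        mv = self.msm(v2)
        u3 = u2 * mv
        v3 = v2 * mu
        u4 = u1 + self.drop_u(self.out_u(u3))
        v4 = v1 + self.drop_v(self.out_v(v3))
        return u4 + v4

    def macs_per_pixel(self) -> int:
        """Dense MACs per pixel of one forward pass (norms/gating excluded)."""
        c = self.cfg.channels
        return 4 * c * c + 2 * self.msm.macs_per_pixel()


def mcg_parameter_count(cfg: MCGConfig) -> int:
    """Exact learnable-scalar count of one MCG block (independent of H, W)."""
    block = MCGBlock(cfg, np.random.default_rng(0))
    return block.n_parameters()
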