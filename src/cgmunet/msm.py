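"""Multi-axis, multi-window MLP block (MsM).

The block splits a feature map into four channel heads and mixes each head
spatially with a small dense layer along one of four fixed-size axes:

* two *local* heads: non-overlapping windows of size ``b`` x ``b`` and
  ``2b`` x ``2b``, mixing the positions inside each window (dense local
  interaction);
* two *global* heads: a ``g`` x ``g`` arrangement of large cells
  (``g`` = ``b`` and ``2b``), mixing the ``g**2`` same-offset pixels across
  cells, i.e. a dilated lattice with stride ``H/g`` x ``W/g`` (sparse global
  interaction).

Every mixing axis has a fixed length (``b**2`` or ``4*b**2``), so one set of
weights accepts any input whose height and width are divisible by ``2b`` —
no resizing or cropping is required, and the cost is linear in the number of
pixels.

Partition helpers operate on plain ``ndarray`` or autodiff :class:`Tensor`
inputs, with or without a leading batch axis; they are pure rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DimensionError
from .nn import Dense, Dropout, LayerNorm, Module, Tensor, concat

__all__ = ["MsMConfig", "MsMBlock", "block_partition", "block_unpartition",
           "grid_partition", "grid_unpartition", "msm_receptive_mask"]


@dataclass(frozen=True)
class MsMConfig:
    """Hyperparameters of one MsM block.

    Parameters
    ----------
    channels:
        Feature channels C; must be divisible by 4 (four heads).
    b:
        Base window size in pixels.  Inputs must have height and width
        divisible by ``2 * b``.
    dropout_rate:
        Dropout applied after the output projection.
    hidden_ratio:
        Width multiplier of the pre-split projection (1 = dimension
        preserving).
    """

    channels: int
    b: int = 2
    dropout_rate: float = 0.1
    hidden_ratio: float = 1.0

    def __post_init__(self):
        if self.channels < 4 or self.channels % 4:
            raise ConfigError(
                f"channels must be a positive multiple of 4, got {self.channels}")
        if self.b < 1:
            raise ConfigError(f"window base b must be >= 1, got {self.b}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got "
                              f"{self.dropout_rate}")
        if self.hidden_channels % 4:
            raise ConfigError(
                f"hidden width {self.hidden_channels} (channels * hidden_ratio) "
                f"must be divisible by 4")

    @property
    def hidden_channels(self) -> int:
        return int(round(self.channels * self.hidden_ratio))


def _spatial(x) -> tuple[int, int, int]:
    if x.ndim == 3:
        h, w, c = x.shape
    elif x.ndim == 4:
        _, h, w, c = x.shape
    else:
        raise DimensionError(f"expected (H, W, C) or (N, H, W, C), got {x.shape}")
    return h, w, c


def _check_divisible(h: int, w: int, size: int) -> None:
    if h % size:
        raise DimensionError(f"height {h} is not divisible by window size {size}")
    if w % size:
        raise DimensionError(f"width {w} is not divisible by window size {size}")


def block_partition(x, window: int):
    """Tile into non-overlapping ``window`` x ``window`` patches.

    Returns a tensor of shape (..., N_w, window**2, C) where window ``(i, j)``
    holds the patch at rows ``[i*window, (i+1)*window)``, columns likewise,
    row-major inside the window.  Pure rearrangement.
    """
    h, w, c = _spatial(x)
    _check_divisible(h, w, window)
    nh, nw = h // window, w // window
    lead = x.shape[:-3]
    t = x.reshape(*lead, nh, window, nw, window, c)
    k = len(lead)
    t = t.transpose(*range(k), k, k + 2, k + 1, k + 3, k + 4)
    return t.reshape(*lead, nh * nw, window * window, c)


def block_unpartition(t, h: int, w: int, window: int):
    """Exact inverse of :func:`block_partition`."""
    nh, nw = h // window, w // window
    c = t.shape[-1]
    if h % window or w % window or t.shape[-3] != nh * nw \
            or t.shape[-2] != window * window:
        raise DimensionError(
            f"windowed tensor {t.shape} is inconsistent with H={h}, W={w}, "
            f"window={window}")
    lead = t.shape[:-3]
    k = len(lead)
    u = t.reshape(*lead, nh, nw, window, window, c)
    u = u.transpose(*range(k), k, k + 2, k + 1, k + 3, k + 4)
    return u.reshape(*lead, h, w, c)


def grid_partition(x, g: int):
    """Partition into a ``g`` x ``g`` arrangement of large cells.

    The image is divided into ``g**2`` cells of size ``(H/g)`` x ``(W/g)``.
    The result has shape (..., (H/g)*(W/g), g**2, C): the first spatial axis
    enumerates within-cell offsets, the second enumerates cells, so fixing an
    offset gathers one pixel per cell — ``g**2`` pixels on a dilated lattice
    with stride ``(H/g, W/g)``.  Equivalently, this is
    :func:`block_partition` with window ``(H/g, W/g)`` followed by swapping
    the two spatial axes.  Pure rearrangement.
    """
    h, w, c = _spatial(x)
    if h % g:
        raise DimensionError(f"height {h} is not divisible by grid size {g}")
    if w % g:
        raise DimensionError(f"width {w} is not divisible by grid size {g}")
    sh, sw = h // g, w // g
    lead = x.shape[:-3]
    k = len(lead)
    t = x.reshape(*lead, g, sh, g, sw, c)
    # (cells_h, off_h, cells_w, off_w) -> (off_h, off_w, cells_h, cells_w)
    t = t.transpose(*range(k), k + 1, k + 3, k, k + 2, k + 4)
    return t.reshape(*lead, sh * sw, g * g, c)


def grid_unpartition(t, h: int, w: int, g: int):
    """Exact inverse of :func:`grid_partition`."""
    sh, sw = h // g, w // g
    c = t.shape[-1]
    if h % g or w % g or t.shape[-3] != sh * sw or t.shape[-2] != g * g:
        raise DimensionError(
            f"gridded tensor {t.shape} is inconsistent with H={h}, W={w}, g={g}")
    lead = t.shape[:-3]
    k = len(lead)
    u = t.reshape(*lead, sh, sw, g, g, c)
    u = u.transpose(*range(k), k + 2, k, k + 3, k + 1, k + 4)
    return u.reshape(*lead, h, w, c)


def msm_receptive_mask(row: int, col: int, h: int, w: int, b: int) -> set:
    """Input pixels that can influence output pixel ``(row, col)``.

    Union of the two enclosing local windows (sizes ``b`` and ``2b``) and the
    two dilated global lattices (strides ``(H/b, W/b)`` and ``(H/2b, W/2b)``).
    """
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"pixel ({row}, {col}) outside a {h}x{w} map")
    _check_divisible(h, w, 2 * b)
    mask: set = set()
    for win in (b, 2 * b):
        r0, c0 = (row // win) * win, (col // win) * win
        mask.update((r, c) for r in range(r0, r0 + win)
                    for c in range(c0, c0 + win))
    for g in (b, 2 * b):
        sh, sw = h // g, w // g
        mask.update((r, c) for r in range(row % sh, h, sh)
                    for c in range(col % sw, w, sw))
    return mask


class _HeadMixer(Module):
    """Dense mixing along the second-to-last (fixed-size) axis, with an
    internal residual: ``t + GELU(Dense(t))``."""

    def __init__(self, axis_len: int, rng: np.random.Generator, dtype):
        super().__init__()
        self.dense = Dense(axis_len, axis_len, rng, dtype)

    def __call__(self, t: Tensor) -> Tensor:
        nd = t.ndim
        axes = tuple(range(nd - 2)) + (nd - 1, nd - 2)
        s = t.transpose(axes)
        s = self.dense(s).gelu()
        return t + s.transpose(axes)


class MsMBlock(Module):
    """The multi-axis, multi-window MLP block.

    Pipeline: LayerNorm -> dense projection -> GELU -> split into four equal
    channel heads -> per-head spatial mixing (two local window scales, two
    global grid scales) -> concatenate -> dense projection -> dropout.
    Output shape equals input shape; parameters depend only on the channel
    width, ``b`` and the hidden ratio, never on H or W.
    """

    def __init__(self, cfg: MsMConfig, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        ch = cfg.hidden_channels
        b = cfg.b
        self.norm = LayerNorm(cfg.channels, dtype=dtype)
        self.pre = Dense(cfg.channels, ch, rng, dtype)
        self.mix_local_1 = _HeadMixer(b * b, rng, dtype)
        self.mix_local_2 = _HeadMixer(4 * b * b, rng, dtype)
        self.mix_global_1 = _HeadMixer(b * b, rng, dtype)
        self.mix_global_2 = _HeadMixer(4 * b * b, rng, dtype)
        self.post = Dense(ch, cfg.channels, rng, dtype)
        self.dropout = Dropout(cfg.dropout_rate, rng)

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        h, w, c = _spatial(x)
        if c != cfg.channels:
            raise DimensionError(f"expected {cfg.channels} channels, got {c}")
        _check_divisible(h, w, 2 * cfg.b)
        b = cfg.b
        ch = cfg.hidden_channels // 4

        t = self.pre(self.norm(x)).gelu()
        heads = [t[..., i * ch:(i + 1) * ch] for i in range(4)]

        l1 = block_unpartition(
            self.mix_local_1(block_partition(heads[0], b)), h, w, b)
        l2 = block_unpartition(
            self.mix_local_2(block_partition(heads[1], 2 * b)), h, w, 2 * b)
        g1 = grid_unpartition(
            self.mix_global_1(grid_partition(heads[2], b)), h, w, b)
        g2 = grid_unpartition(
            self.mix_global_2(grid_partition(heads[3], 2 * b)), h, w, 2 * b)

        out = self.post(concat([l1, l2, g1, g2], axis=-1))
        return self.dropout(out)

    def macs_per_pixel(self) -> int:
        """Dense-layer multiply-accumulates per input pixel (norms excluded)."""
        cfg = self.cfg
        ch = cfg.hidden_channels
        mixing = (ch // 4) * (cfg.b ** 2 + 4 * cfg.b ** 2) * 2
        return cfg.channels * ch + mixing + ch * cfg.channels
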