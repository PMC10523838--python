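"""Hierarchical shifted-window (Swin) transformer backbone.

The backbone tokenises a grayscale image into non-overlapping 4x4 patches,
projects each patch to an embedding dimension ``C`` (default 96), and runs
four stages of window-based multi-head self-attention blocks.  Between
stages a patch-merging layer concatenates 2x2 neighbouring tokens (4C
channels) and projects them to 2C, halving the spatial resolution, so the
stages produce a feature hierarchy at H/4, H/8, H/16 and H/32 with channel
widths C, 2C, 4C and 8C.

Within a stage, blocks alternate between regular window attention (W-MSA)
and shifted window attention (SW-MSA): the token grid is cyclically rolled
by half a window before partitioning, and an attention mask keeps tokens
that were not neighbours before the roll from attending to each other.
This gives cross-window information flow at linear cost in image size.

Everything here runs on the package's own autograd tensors, so the same
code path serves both inference and training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import LayerNorm, Linear, Mlp, Module

__all__ = [
    "BackboneConfig",
    "TokenGrid",
    "AttentionWindowSet",
    "patch_partition",
    "tokens_to_image",
    "linear_embed",
    "cyclic_shift",
    "partition_windows",
    "merge_windows",
    "build_attention_mask",
    "window_attention",
    "WindowAttention",
    "SwinBlock",
    "PatchMerging",
    "SwinBackbone",
    "swin_block",
    "patch_merge",
    "backbone_forward",
]

_NEG_INF = np.float32(-1e9)


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyper-parameters.

    ``embed_dim`` is the stage-1 channel width C; ``depths`` and
    ``num_heads`` list one entry per stage.  ``window_size`` is the side
    length M of the attention windows, in tokens.
    """

    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple[int, ...] = (2, 2, 6, 2)
    num_heads: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    mlp_ratio: float = 4.0
    use_relative_position_bias: bool = True

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.num_heads) != 4:
            raise ValueError("depths and num_heads must list exactly four stages")
        if self.embed_dim <= 0 or self.patch_size <= 0 or self.window_size <= 0:
            raise ValueError("embed_dim, patch_size and window_size must be positive")
        for s, h in enumerate(self.num_heads):
            if (self.embed_dim * 2 ** s) % h:
                raise ValueError(f"stage {s + 1} channels not divisible by {h} heads")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths"] = list(self.depths)
        d["num_heads"] = list(self.num_heads)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        d = dict(d)
        d["depths"] = tuple(d["depths"])
        d["num_heads"] = tuple(d["num_heads"])
        return cls(**d)


@dataclass
class TokenGrid:
    """A 2D grid of token vectors at some backbone stage."""

    tokens: np.ndarray  # (H_t, W_t, D)
    stage: int = 1

    def __post_init__(self):
        self.tokens = np.asarray(self.tokens, dtype=np.float32)
        if self.tokens.ndim != 3:
            raise ValueError("tokens must be a (rows, cols, channels) array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tokens.shape


@dataclass
class AttentionWindowSet:
    """Windows tiling a (padded) token grid, plus the SW-MSA mask."""

    windows: np.ndarray  # (n_windows, M*M, D)
    window_size: int
    shift: tuple[int, int]
    grid_shape: tuple[int, int]          # unpadded (H_t, W_t)
    padded_shape: tuple[int, int]
    attention_mask: np.ndarray | None = None  # (n_windows, M*M, M*M) additive


# ---------------------------------------------------------------------------
# functional token-grid operations


def patch_partition(image: np.ndarray, patch_size: int = 4) -> TokenGrid:
    """Split a grayscale image into flattened non-overlapping patches.

    The image is zero-padded on the right/bottom to a multiple of
    ``patch_size``; each token is the row-major flattened patch, so the
    raw token dimension is ``patch_size**2`` for single-channel input.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2D array")
    p = int(patch_size)
    h, w = image.shape
    hp, wp = -(-h // p) * p, -(-w // p) * p
    padded = np.pad(image, ((0, hp - h), (0, wp - w)))
    tokens = padded.reshape(hp // p, p, wp // p, p).transpose(0, 2, 1, 3).reshape(hp // p, wp // p, p * p)
    return TokenGrid(tokens, stage=1)


def tokens_to_image(grid: TokenGrid, patch_size: int = 4) -> np.ndarray:
    """Inverse of :func:`patch_partition` (returns the padded image)."""
    ht, wt, d = grid.tokens.shape
    p = int(patch_size)
    if d != p * p:
        raise ValueError(f"token dim {d} does not match patch_size {p}")
    return grid.tokens.reshape(ht, wt, p, p).transpose(0, 2, 1, 3).reshape(ht * p, wt * p)


def linear_embed(grid: TokenGrid, embed_dim: int = 96, *, weight: np.ndarray | None = None,
                 bias: np.ndarray | None = None, seed: int = 0) -> TokenGrid:
    """Project raw patch tokens to ``embed_dim`` channels, shared across positions."""
    ht, wt, d = grid.tokens.shape
    if weight is None:
        rng = np.random.default_rng(seed)
        weight = rng.normal(0.0, 0.02, size=(d, embed_dim)).astype(np.float32)
    weight = np.asarray(weight, dtype=np.float32)
    if weight.shape[0] != d:
        raise ValueError(f"weight expects {weight.shape[0]} input channels, tokens have {d}")
    out = grid.tokens @ weight
    if bias is not None:
        out = out + np.asarray(bias, dtype=np.float32)
    return TokenGrid(out, stage=1)


def cyclic_shift(tokens: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Roll the token grid cyclically along its two spatial axes."""
    tokens = np.asarray(tokens)
    if any(abs(s) >= n for s, n in zip(shift, tokens.shape[:2])):
        raise ValueError("shift magnitude must be smaller than grid dimensions")
    return np.roll(tokens, shift, axis=(0, 1))


def build_attention_mask(h: int, w: int, window_size: int,
                         shift: tuple[int, int]) -> np.ndarray | None:
    """Additive attention mask for (shifted) windows over an ``h x w`` grid.

    The grid is zero-padded to window multiples and then cyclically rolled
    by ``shift`` (the roll actually applied to the tokens).  Tokens are
    labelled by the contiguous region they occupy after the roll; cells
    added by padding get a label of their own.  Pairs with different
    labels receive ``-1e9`` so their post-softmax weight is numerically
    zero.  Returns ``None`` when no mask is needed.
    """
    m = int(window_size)
    hp, wp = -(-h // m) * m, -(-w // m) * m
    s_r, s_c = (-shift[0]) % m, (-shift[1]) % m
    if s_r == 0 and s_c == 0 and (hp, wp) == (h, w):
        return None

    def _slices(n: int, s: int):
        if s == 0:
            return (slice(0, n),)
        return (slice(0, n - m), slice(n - m, n - s), slice(n - s, n))

    # region labels are written in post-roll coordinates (standard Swin slices)
    region = np.zeros((hp, wp), dtype=np.int64)
    cnt = 1
    for rs in _slices(hp, s_r):
        for cs in _slices(wp, s_c):
            region[rs, cs] = cnt
            cnt += 1
    # padding cells, marked pre-roll and carried through the roll
    pad_mask = np.zeros((hp, wp), dtype=bool)
    pad_mask[h:, :] = True
    pad_mask[:, w:] = True
    if shift != (0, 0):
        pad_mask = np.roll(pad_mask, shift, axis=(0, 1))
    label = np.where(pad_mask, np.int64(10 ** 6), region)
    win = label.reshape(hp // m, m, wp // m, m).transpose(0, 2, 1, 3).reshape(-1, m * m)
    diff = win[:, :, None] != win[:, None, :]
    return np.where(diff, _NEG_INF, np.float32(0.0))


def partition_windows(tokens: np.ndarray, window_size: int,
                      shift: tuple[int, int] = (0, 0)) -> AttentionWindowSet:
    """Pad to window multiples, cyclically shift, and tile into MxM windows."""
    tokens = np.asarray(tokens, dtype=np.float32)
    h, w, d = tokens.shape
    m = int(window_size)
    hp, wp = -(-h // m) * m, -(-w // m) * m
    padded = np.pad(tokens, ((0, hp - h), (0, wp - w), (0, 0)))
    if shift != (0, 0):
        padded = cyclic_shift(padded, shift)
    wins = padded.reshape(hp // m, m, wp // m, m, d).transpose(0, 2, 1, 3, 4).reshape(-1, m * m, d)
    mask = build_attention_mask(h, w, m, shift)
    return AttentionWindowSet(wins, m, tuple(shift), (h, w), (hp, wp), mask)


def merge_windows(ws: AttentionWindowSet, windows: np.ndarray | None = None) -> np.ndarray:
    """Undo :func:`partition_windows`: re-tile, unroll the shift, crop padding."""
    wins = ws.windows if windows is None else np.asarray(windows)
    m = ws.window_size
    hp, wp = ws.padded_shape
    h, w = ws.grid_shape
    d = wins.shape[-1]
    grid = wins.reshape(hp // m, wp // m, m, m, d).transpose(0, 2, 1, 3, 4).reshape(hp, wp, d)
    if ws.shift != (0, 0):
        grid = cyclic_shift(grid, tuple(-s for s in ws.shift))
    return grid[:h, :w]


# ---------------------------------------------------------------------------
# trainable modules


def _relative_position_index(m: int) -> np.ndarray:
    """Pairwise relative-offset index into a (2M-1)^2 bias table."""
    coords = np.stack(np.meshgrid(np.arange(m), np.arange(m), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]
    rel = rel.transpose(1, 2, 0) + (m - 1)
    return rel[:, :, 0] * (2 * m - 1) + rel[:, :, 1]


class WindowAttention(Module):
    """Multi-head self-attention within MxM windows, optional relative bias."""

    def __init__(self, dim: int, num_heads: int, window_size: int,
                 rng: np.random.Generator, use_relative_position_bias: bool = True):
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by {num_heads} heads")
        self.dim = dim
        self.num_heads = num_heads
        self.window_size = int(window_size)
        self.scale = (dim // num_heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.use_relative_position_bias = use_relative_position_bias
        if use_relative_position_bias:
            m = self.window_size
            table = rng.normal(0.0, 0.02, size=((2 * m - 1) ** 2, num_heads))
            self.relative_position_bias_table = Tensor(table, requires_grad=True)
            self._rel_index = _relative_position_index(m)

    def __call__(self, windows: Tensor, mask: np.ndarray | None = None,
                 window_size: int | None = None) -> Tensor:
        nw, n, d = windows.shape
        h = self.num_heads
        hd = d // h
        qkv = self.qkv(windows)                       # (nw, n, 3d)
        qkv = qkv.reshape(nw, n, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3, nw, h, n, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = ag.matmul(Tensor(np.float32(self.scale)) * q, k.transpose(0, 1, 3, 2))  # (nw, h, n, n)
        if self.use_relative_position_bias:
            m = window_size if window_size is not None else self.window_size
            idx = self._rel_index if m == self.window_size else _relative_position_index(m)
            if n == m * m:
                bias = ag.embedding(self.relative_position_bias_table, idx.reshape(-1))
                bias = bias.reshape(m * m, m * m, h).transpose(2, 0, 1)  # (h, n, n)
                attn = attn + bias
        if mask is not None:
            attn = attn + Tensor(mask[:, None, :, :])
        attn = ag.softmax(attn, axis=-1)
        out = ag.matmul(attn, v)                       # (nw, h, n, hd)
        out = out.transpose(0, 2, 1, 3).reshape(nw, n, d)
        return self.proj(out)


class SwinBlock(Module):
    """LN -> (S)W-MSA -> residual -> LN -> MLP -> residual on an (H, W, C) grid."""

    def __init__(self, dim: int, num_heads: int, window_size: int, shifted: bool,
                 mlp_ratio: float, rng: np.random.Generator,
                 use_relative_position_bias: bool = True):
        self.dim = dim
        self.window_size = int(window_size)
        self.shifted = bool(shifted)
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, num_heads, window_size, rng,
                                    use_relative_position_bias)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def _effective(self, h: int, w: int) -> tuple[int, int]:
        """Clamp the window to the grid; drop the shift when one window suffices."""
        ws = min(self.window_size, h, w)
        shift = ws // 2 if self.shifted and (h > ws or w > ws) else 0
        return ws, shift

    def __call__(self, x: Tensor) -> Tensor:
        h, w, d = x.shape
        ws, shift = self._effective(h, w)
        shortcut = x
        y = self.norm1(x)
        hp, wp = -(-h // ws) * ws, -(-w // ws) * ws
        if (hp, wp) != (h, w):
            y = ag.pad(y, ((0, hp - h), (0, wp - w), (0, 0)))
        if shift:
            y = ag.roll2d(y, (-shift, -shift))
        y = y.reshape(hp // ws, ws, wp // ws, ws, d).transpose(0, 2, 1, 3, 4)
        y = y.reshape((hp // ws) * (wp // ws), ws * ws, d)
        mask = build_attention_mask(h, w, ws, (-shift, -shift))
        y = self.attn(y, mask=mask, window_size=ws)
        y = y.reshape(hp // ws, wp // ws, ws, ws, d).transpose(0, 2, 1, 3, 4).reshape(hp, wp, d)
        if shift:
            y = ag.roll2d(y, (shift, shift))
        if (hp, wp) != (h, w):
            y = y[:h, :w]
        x = shortcut + y
        return x + self.mlp(self.norm2(x))


class PatchMerging(Module):
    """Concatenate 2x2 neighbouring tokens (4C) and project to 2C."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dim = dim
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        h, w, d = x.shape
        if h % 2 or w % 2:
            x = ag.pad(x, ((0, h % 2), (0, w % 2), (0, 0)))
        x0 = x[0::2, 0::2, :]
        x1 = x[1::2, 0::2, :]
        x2 = x[0::2, 1::2, :]
        x3 = x[1::2, 1::2, :]
        merged = ag.concat([x0, x1, x2, x3], axis=-1)
        return self.reduction(self.norm(merged))


class PatchEmbed(Module):
    """Patch partition + shared linear embedding to C channels."""

    def __init__(self, patch_size: int, embed_dim: int, rng: np.random.Generator):
        self.patch_size = int(patch_size)
        self.proj = Linear(patch_size * patch_size, embed_dim, rng)
        self.norm = LayerNorm(embed_dim)

    def __call__(self, image: np.ndarray) -> Tensor:
        grid = patch_partition(image, self.patch_size)
        return self.norm(self.proj(Tensor(grid.tokens)))


class SwinBackbone(Module):
    """Four-stage hierarchical backbone producing H/4 ... H/32 feature maps."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        self.config = config
        c = config.embed_dim
        self.patch_embed = PatchEmbed(config.patch_size, c, rng)
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerging] = []
        self.out_norms: list[LayerNorm] = []
        for s in range(4):
            dim = c * 2 ** s
            blocks = [
                SwinBlock(dim, config.num_heads[s], config.window_size,
                          shifted=(i % 2 == 1), mlp_ratio=config.mlp_ratio, rng=rng,
                          use_relative_position_bias=config.use_relative_position_bias)
                for i in range(config.depths[s])
            ]
            self.stages.append(blocks)
            self.out_norms.append(LayerNorm(dim))
            if s < 3:
                self.merges.append(PatchMerging(dim, rng))

    @property
    def stage_dims(self) -> tuple[int, ...]:
        c = self.config.embed_dim
        return tuple(c * 2 ** s for s in range(4))

    def __call__(self, image: np.ndarray) -> list[Tensor]:
        x = self.patch_embed(image)
        features: list[Tensor] = []
        for s in range(4):
            for block in self.stages[s]:
                x = block(x)
            features.append(self.out_norms[s](x))
            if s < 3:
                x = self.merges[s](x)
        return features


# ---------------------------------------------------------------------------
# thin functional wrappers over the modules


def window_attention(ws: AttentionWindowSet, num_heads: int,
                     seed: int = 0, use_relative_position_bias: bool = False) -> AttentionWindowSet:
    """Run multi-head window attention on an :class:`AttentionWindowSet`."""
    d = ws.windows.shape[-1]
    attn = WindowAttention(d, num_heads, ws.window_size, np.random.default_rng(seed),
                           use_relative_position_bias)
    out = attn(Tensor(ws.windows), mask=ws.attention_mask)
    return AttentionWindowSet(out.data, ws.window_size, ws.shift, ws.grid_shape,
                              ws.padded_shape, ws.attention_mask)


def swin_block(tokens: np.ndarray, shifted: bool, num_heads: int = 3,
               window_size: int = 7, mlp_ratio: float = 4.0, seed: int = 0) -> np.ndarray:
    """One forward Swin block on a raw (H, W, C) token array."""
    tokens = np.asarray(tokens, dtype=np.float32)
    block = SwinBlock(tokens.shape[-1], num_heads, window_size, shifted, mlp_ratio,
                      np.random.default_rng(seed))
    return block(Tensor(tokens)).data


def patch_merge(tokens: np.ndarray, seed: int = 0) -> np.ndarray:
    """Forward patch merging on a raw (H, W, C) token array -> (H/2, W/2, 2C)."""
    tokens = np.asarray(tokens, dtype=np.float32)
    merge = PatchMerging(tokens.shape[-1], np.random.default_rng(seed))
    return merge(Tensor(tokens)).data


def backbone_forward(image: np.ndarray, config: BackboneConfig | None = None,
                     seed: int = 0) -> list[np.ndarray]:
    """Forward a grayscale image through a freshly initialised backbone.

    Returns the four stage feature maps as plain arrays, at resolutions
    ceil(H/4) ... ceil(H/32) with channels C, 2C, 4C, 8C.
    """
    config = config or BackboneConfig()
    model = SwinBackbone(config, np.random.default_rng(seed))
    return [t.data for t in model(np.asarray(image, dtype=np.float32))]
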