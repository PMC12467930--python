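"""Hybrid dual-branch encoder.

A residual 3D CNN pathway extracts local structure and a 3D shifted-window
transformer pathway models global context; both end at 1/8 of the input
resolution and are fused by channel concatenation + 1x1x1 convolution into
the shared latent volume.  The CNN pathway also exposes a skip pyramid at
/1, /2 and /4 resolution for the segmentation decoder.

Swin layout: an initial stride-2 patch embedding followed by up to three
stride-2 patch mergings between stages, so the token grid reaches /8; any
mergings not consumed by intermediate stages are appended after the last
stage.  Windows use learned relative-position bias, cyclic shifts of half a
window on alternating blocks, and the standard attention mask that stops
wrapped tokens from attending across the volume boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    BatchNorm3d,
    Conv3d,
    LayerNorm,
    Linear,
    Module,
    PointwiseConv3d,
    Tensor,
    as_tensor,
    concatenate,
)
from .nn import functional as F
from .nn.functional import embedding_lookup

__all__ = ["EncoderConfig", "HybridEncoder", "window_partition", "window_reverse"]


@dataclass
class EncoderConfig:
    in_channels: int = 32  # C' from the fusion stage
    cnn_widths: tuple[int, int, int] = (32, 64, 128)  # stages at /2, /4, /8
    branch_channels: int = 128  # C'': each branch's output width
    out_channels: int = 128  # C_out of the fused latent
    window: int = 8
    swin_dim: int = 32  # stage-1 token width (doubles at each merge)
    swin_depths: tuple[int, ...] = (2, 2, 2, 2)
    swin_heads: tuple[int, ...] = (2, 4, 8, 8)
    skips: str = "cnn"  # skip pyramid source; "cnn" per default layout

    def __post_init__(self):
        if len(self.swin_depths) != len(self.swin_heads):
            raise ValueError("swin_depths and swin_heads must have equal length")
        if not 1 <= len(self.swin_depths) <= 4:
            raise ValueError("between 1 and 4 swin stages are supported")


# ----------------------------------------------------------- CNN branch


class ResidualBlock(Module):
    """Pre-activation residual block: x + Conv(ReLU(BN(Conv(ReLU(BN(x)))))).

    With the convolution weights zeroed the block is exactly the identity.
    """

    def __init__(self, channels: int, rng):
        super().__init__()
        self.bn1 = BatchNorm3d(channels)
        self.conv1 = Conv3d(channels, channels, 3, rng)
        self.bn2 = BatchNorm3d(channels)
        self.conv2 = Conv3d(channels, channels, 3, rng)

    def forward(self, x):
        h = self.conv1(self.bn1(x).relu())
        h = self.conv2(self.bn2(h).relu())
        return x + h


class Downsample(Module):
    """Stride-2 2x2x2 "convolution" as space-to-depth + channel projection."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.proj = PointwiseConv3d(8 * c_in, c_out, rng)

    def forward(self, x):
        return self.proj(F.patchify(x, 2))


class CnnBranch(Module):
    def __init__(self, cfg: EncoderConfig, rng):
        super().__init__()
        w = cfg.cnn_widths
        self.stem = Conv3d(cfg.in_channels, w[0], 3, rng)
        self.stem_bn = BatchNorm3d(w[0])
        prev = w[0]
        for i, width in enumerate(w):
            setattr(self, f"down{i}", Downsample(prev, width, rng))
            setattr(self, f"res{i}a", ResidualBlock(width, rng))
            setattr(self, f"res{i}b", ResidualBlock(width, rng))
            prev = width
        self.head = PointwiseConv3d(w[-1], cfg.branch_channels, rng)

    def forward(self, x) -> tuple[Tensor, list[Tensor]]:
        if any(s % 8 for s in x.shape[2:]):
            raise ValueError(
                f"spatial shape {x.shape[2:]} not divisible by 8; pad the input first"
            )
        h = self.stem_bn(self.stem(x)).relu()
        skips = [h]  # /1
        for i in range(3):
            h = getattr(self, f"down{i}")(h)
            h = getattr(self, f"res{i}a")(h)
            h = getattr(self, f"res{i}b")(h)
            if i < 2:
                skips.append(h)  # /2, /4
        return self.head(h), skips


# ---------------------------------------------------------- Swin branch


def window_partition(x: Tensor, grid: tuple[int, int, int], window: tuple[int, int, int]) -> Tensor:
    """(N, Gh*Gw*Gd, C) tokens -> (N*nW, wh*ww*wd, C) window tokens."""
    n, _, c = x.shape
    gh, gw, gd = grid
    wh, ww, wd = window
    t = x.reshape(n, gh // wh, wh, gw // ww, ww, gd // wd, wd, c)
    t = t.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return t.reshape(-1, wh * ww * wd, c)


def window_reverse(x: Tensor, grid: tuple[int, int, int], window: tuple[int, int, int], n: int) -> Tensor:
    """Inverse of :func:`window_partition`."""
    gh, gw, gd = grid
    wh, ww, wd = window
    t = x.reshape(n, gh // wh, gw // ww, gd // wd, wh, ww, wd, -1)
    t = t.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return t.reshape(n, gh * gw * gd, t.shape[-1])


def _relative_position_index(window: tuple[int, int, int]) -> np.ndarray:
    coords = np.stack(
        np.meshgrid(*[np.arange(w) for w in window], indexing="ij"), axis=0
    ).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (3, T, T)
    rel = rel + np.array(window)[:, None, None] - 1
    sizes = [2 * w - 1 for w in window]
    return (rel[0] * sizes[1] * sizes[2] + rel[1] * sizes[2] + rel[2]).astype(int)


def _shift_attention_mask(grid, window, shift) -> np.ndarray | None:
    """Standard shifted-window mask: -inf-like penalty between tokens whose
    pre-shift regions differ, per window. Returns (nW, T, T) or None."""
    if all(s == 0 for s in shift):
        return None
    gh, gw, gd = grid
    region = np.zeros(grid, dtype=int)
    cnt = 0
    slices = []
    for g, w, s in zip(grid, window, shift):
        slices.append([slice(0, g - w), slice(g - w, g - s), slice(g - s, g)])
    for sh in slices[0]:
        for sw in slices[1]:
            for sd in slices[2]:
                region[sh, sw, sd] = cnt
                cnt += 1
    region = np.roll(region, tuple(-s for s in shift), axis=(0, 1, 2))
    tokens = region.reshape(
        gh // window[0], window[0], gw // window[1], window[1], gd // window[2], window[2]
    ).transpose(0, 2, 4, 1, 3, 5).reshape(-1, int(np.prod(window)))
    mask = (tokens[:, :, None] != tokens[:, None, :]) * -1e9
    return mask


class WindowAttention(Module):
    def __init__(self, dim: int, heads: int, window: tuple[int, int, int], rng):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.window = dim, heads, window
        self.scale = (dim // heads) ** -0.5
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        n_bias = int(np.prod([2 * w - 1 for w in window]))
        from .nn import Parameter

        self.rel_bias = Parameter(rng.normal(0, 0.02, size=(n_bias, heads)))
        self._rel_index = _relative_position_index(window)

    def forward(self, xw: Tensor, mask: np.ndarray | None = None) -> Tensor:
        b, t, c = xw.shape
        h = self.heads
        hd = c // h
        qkv = self.qkv(xw).reshape(b, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale  # (b, h, t, t)
        bias = embedding_lookup(self.rel_bias, self._rel_index)  # (t, t, h)
        attn = attn + bias.transpose(2, 0, 1).reshape(1, h, t, t)
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(b // nw, nw, h, t, t) + Tensor(mask[None, :, None])
            attn = attn.reshape(b, h, t, t)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, c)
        return self.proj(out)


class SwinBlock(Module):
    """W-MSA / SW-MSA block with post-normalization and an MLP sublayer."""

    def __init__(self, dim: int, heads: int, window: int, shifted: bool, rng, mlp_ratio: int = 2):
        super().__init__()
        self.window_size = window
        self.shifted = shifted
        self.attn = None  # built lazily once the grid is known
        self._dim, self._heads, self._rng = dim, heads, rng
        self.norm1 = LayerNorm(dim)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = Linear(mlp_ratio * dim, dim, rng)
        self._attn_cache: dict = {}

    def _window_for(self, grid):
        return tuple(min(self.window_size, g) for g in grid)

    def forward(self, x: Tensor, grid: tuple[int, int, int]) -> Tensor:
        window = self._window_for(grid)
        if self.attn is None:
            self.attn = WindowAttention(self._dim, self._heads, window, self._rng)
        elif self.attn.window != window:
            raise ValueError(
                f"block built for window {self.attn.window}, got grid requiring {window}"
            )
        n = x.shape[0]
        c = x.shape[-1]
        # pad the token grid up to window multiples (cropped back below)
        pgrid = tuple(-(-g // w) * w for g, w in zip(grid, window))
        h = x
        if pgrid != tuple(grid):
            vol = h.reshape(n, *grid, c)
            pw = [(0, 0)] + [(0, p - g) for p, g in zip(pgrid, grid)] + [(0, 0)]
            h = vol.pad(pw).reshape(n, -1, c)
        shift = tuple(w // 2 if (self.shifted and w < g) else 0 for w, g in zip(window, pgrid))
        if any(shift):
            h = h.reshape(n, *pgrid, c).roll(tuple(-s for s in shift), (1, 2, 3)).reshape(n, -1, c)
        hw = window_partition(h, pgrid, window)
        key = (pgrid, window, shift)
        if key not in self._attn_cache:
            self._attn_cache[key] = _shift_attention_mask(pgrid, window, shift)
        hw = self.attn(hw, self._attn_cache[key])
        h = window_reverse(hw, pgrid, window, n)
        if any(shift):
            h = h.reshape(n, *pgrid, c).roll(shift, (1, 2, 3)).reshape(n, -1, c)
        if pgrid != tuple(grid):
            vol = h.reshape(n, *pgrid, c)
            sl = (slice(None),) + tuple(slice(0, g) for g in grid) + (slice(None),)
            h = vol[sl].reshape(n, -1, c)
        x = self.norm1(x + h)  # post-attention layer normalization
        m = self.fc2(self.fc1(x).relu())
        return self.norm2(x + m)


class PatchMerge(Module):
    """2x2x2 token merging: concatenate neighbours, project channels."""

    def __init__(self, c_in: int, c_out: int, rng):
        super().__init__()
        self.proj = Linear(8 * c_in, c_out, rng)
        self.norm = LayerNorm(8 * c_in)

    def forward(self, x: Tensor, grid):
        n, _, c = x.shape
        vol = x.reshape(n, *grid, c).transpose(0, 4, 1, 2, 3)
        merged = F.patchify(vol, 2)  # (n, 8c, g/2...)
        new_grid = tuple(g // 2 for g in grid)
        tokens = merged.reshape(n, 8 * c, -1).transpose(0, 2, 1)
        return self.proj(self.norm(tokens)), new_grid


class SwinBranch(Module):
    def __init__(self, cfg: EncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.embed = Downsample(cfg.in_channels, cfg.swin_dim, rng)  # /2 patch embedding
        dims = [cfg.swin_dim * 2**i for i in range(len(cfg.swin_depths))]
        self.dims = dims
        n_stages = len(cfg.swin_depths)
        self.blocks: list[list[SwinBlock]] = []
        for si, (depth, heads) in enumerate(zip(cfg.swin_depths, cfg.swin_heads)):
            stage = []
            for bi in range(depth):
                blk = SwinBlock(dims[si], heads, cfg.window, shifted=bool(bi % 2), rng=rng)
                setattr(self, f"s{si}b{bi}", blk)
                stage.append(blk)
            self.blocks.append(stage)
        # merges between stages; leftovers appended after the last stage so the
        # total reduction is always /8 (=/2 embed * three /2 merges)
        n_between = min(n_stages - 1, 2)
        self._n_merges = 2  # merges needed after the /2 embedding: -> /4 -> /8
        merge_dims = []
        prev = dims[0]
        for i in range(self._n_merges):
            nxt = dims[i + 1] if i + 1 < len(dims) else prev * 2
            merge_dims.append((prev, nxt))
            prev = nxt
        self.final_dim = prev
        for i, (ci, co) in enumerate(merge_dims):
            setattr(self, f"merge{i}", PatchMerge(ci, co, rng))
        self.head = Linear(self.final_dim, cfg.branch_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        if any(s % 8 for s in x.shape[2:]):
            raise ValueError(
                f"spatial shape {x.shape[2:]} not divisible by 8; pad the input first"
            )
        n = x.shape[0]
        vol = self.embed(x)  # (n, dim, /2)
        grid = vol.shape[2:]
        tokens = vol.reshape(n, self.dims[0], -1).transpose(0, 2, 1)
        merges_done = 0
        n_stages = len(self.blocks)
        for si, stage in enumerate(self.blocks):
            for blk in stage:
                tokens = blk(tokens, grid)
            if si < n_stages - 1 and merges_done < self._n_merges:
                tokens, grid = getattr(self, f"merge{merges_done}")(tokens, grid)
                merges_done += 1
        while merges_done < self._n_merges:
            tokens, grid = getattr(self, f"merge{merges_done}")(tokens, grid)
            merges_done += 1
        tokens = self.head(tokens)
        c = self.cfg.branch_channels
        return tokens.transpose(0, 2, 1).reshape(n, c, *grid)


# ---------------------------------------------------------------- fused


class HybridEncoder(Module):
    """CNN + shifted-window transformer branches fused into the latent volume."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.cnn = CnnBranch(cfg, rng)
        self.swin = SwinBranch(cfg, rng)
        self.fuse = PointwiseConv3d(2 * cfg.branch_channels, cfg.out_channels, rng)

    def fuse_branches(self, f_cnn: Tensor, f_tr: Tensor) -> Tensor:
        if f_cnn.shape[2:] != f_tr.shape[2:]:
            raise ValueError(
                f"branch spatial shapes differ: {f_cnn.shape[2:]} vs {f_tr.shape[2:]}"
            )
        return self.fuse(concatenate([f_cnn, f_tr], axis=1))

    def forward(self, fused: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Returns (latent at /8, skip pyramid at [/1, /2, /4])."""
        fused = as_tensor(fused)
        f_cnn, skips = self.cnn(fused)
        f_tr = self.swin(fused)
        return self.fuse_branches(f_cnn, f_tr), skips
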