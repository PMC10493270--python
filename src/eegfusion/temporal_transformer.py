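"""Per-channel CPD-map feature extractor: a small-data vision transformer
with Shifted Patch Tokenization (SPT) and Locality Self-Attention (LSA).

SPT concatenates diagonally shifted copies of the input along the channel
axis before patch embedding; LSA masks the diagonal of the query-key score
matrix to -inf and replaces the fixed sqrt(d_k) softmax scale with a
learnable per-head temperature.  With an empty shift set, the temperature
pinned to sqrt(d_k) and the mask off, the module reduces numerically to a
standard ViT block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (NEG_INF, LayerNorm, Linear, Module, Tensor, as_tensor,
                 concat, gelu, parameter, softmax)

#: Default SPT shift set: the four half-patch diagonal translations,
#: expressed in units of half the patch size.
DEFAULT_SHIFTS: tuple[tuple[int, int], ...] = ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class TTMConfig:
    patch_size: int = 8
    embed_dim: int = 64
    depth: int = 4
    n_heads: int = 4
    mlp_ratio: float = 2.0
    n_classes: int = 3
    shift_set: tuple[tuple[int, int], ...] = DEFAULT_SHIFTS
    mask_diagonal: bool = True

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.patch_size < 1 or self.depth < 1:
            raise ValueError("patch_size and depth must be >= 1")

    @classmethod
    def test_profile(cls, **overrides) -> "TTMConfig":
        """Smaller configuration for reduced-epoch runs on one CPU."""
        kwargs = dict(patch_size=8, embed_dim=32, depth=2, n_heads=4)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class TTMOutput:
    features: Tensor    # (batch, embed_dim) pre-classifier class-token embedding
    logits: Tensor      # (batch, n_classes)


def pad_to_multiple(images: np.ndarray, p: int) -> np.ndarray:
    """Reflect-pad trailing (H, W) axes up to multiples of ``p``."""
    h, w = images.shape[-2:]
    if h < 1 or w < 1:
        raise ValueError("empty image")
    ph = (-h) % p
    pw = (-w) % p
    if ph >= h or pw >= w:
        raise ValueError(f"patch size {p} too large for image {h}x{w} to reflect-pad")
    pad = [(0, 0)] * (images.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(images, pad, mode="reflect") if (ph or pw) else images


def _translate(images: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift trailing (H, W) axes by (dy, dx) pixels, zero-filling borders."""
    out = np.zeros_like(images)
    h, w = images.shape[-2:]
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    yo = slice(max(-dy, 0), h + min(-dy, 0))
    xo = slice(max(-dx, 0), w + min(-dx, 0))
    out[..., ys, xs] = images[..., yo, xo]
    return out


def shifted_patch_tokenize(images: np.ndarray, patch_size: int,
                           shift_set=DEFAULT_SHIFTS) -> np.ndarray:
    """Raw (pre-projection) SPT tokens.

    ``images`` is (H, W) or (batch, H, W) with H, W multiples of
    ``patch_size``; shifts are in units of half the patch size.  Returns
    (..., n_tokens, patch_size**2 * (1 + len(shift_set))) where
    n_tokens = (H / p) * (W / p).
    """
    squeeze = images.ndim == 2
    if squeeze:
        images = images[None]
    if images.ndim != 3:
        raise ValueError("images must be (H, W) or (batch, H, W)")
    b, h, w = images.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image dims {h}x{w} not divisible by patch size {p}")
    if p > h or p > w:
        raise ValueError("patch_size exceeds image dimensions")
    half = p // 2
    stack = [images] + [_translate(images, dy * half, dx * half)
                        for dy, dx in shift_set]
    planes = np.stack(stack, axis=1)                      # (b, C, h, w)
    c = planes.shape[1]
    planes = planes.reshape(b, c, h // p, p, w // p, p)
    tokens = planes.transpose(0, 2, 4, 3, 5, 1).reshape(b, (h // p) * (w // p),
                                                        p * p * c)
    return tokens[0] if squeeze else tokens


def locality_self_attention(q: Tensor, k: Tensor, v: Tensor, temperature,
                            mask_diagonal: bool = True) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention with optional diagonal masking.

    ``q``, ``k``, ``v`` are (..., tokens, head_dim); ``temperature`` divides
    the score matrix (a positive scalar, array, or Tensor — pass sqrt(d_k)
    for the standard fixed scale).  Returns ``(output, weights)``; weight
    rows sum to 1 and the diagonal is exactly 0 when masked.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    n_tok = q.shape[-2]
    if mask_diagonal and n_tok < 2:
        raise ValueError("diagonal masking undefined for a single token")
    scores = (q @ k.swapaxes(-1, -2)) / temperature
    if mask_diagonal:
        mask = np.zeros((n_tok, n_tok), dtype=scores.dtype)
        np.fill_diagonal(mask, NEG_INF)
        scores = scores + Tensor(mask)
    weights = softmax(scores, axis=-1)
    return weights @ v, weights


class MultiHeadLSA(Module):
    """Multi-head locality self-attention with learnable per-head temperature."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mask_diagonal: bool = True):
        self.dim, self.n_heads = dim, n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        # parameterized on the log scale so the temperature stays positive
        self.log_temperature = parameter(
            np.full((n_heads, 1, 1), 0.5 * np.log(self.head_dim)))
        self.mask_diagonal = mask_diagonal

    @property
    def temperature(self) -> Tensor:
        return self.log_temperature.exp()

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)        # (3, b, heads, t, head_dim)
        q, k, v = qkv[0], qkv[1], qkv[2]
        out, _ = locality_self_attention(q, k, v, self.temperature,
                                         self.mask_diagonal)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)


class EncoderBlock(Module):
    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator, mask_diagonal: bool = True):
        hidden = int(round(dim * mlp_ratio))
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadLSA(dim, n_heads, rng, mask_diagonal)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(gelu(self.fc1(self.norm2(x))))


class TTM(Module):
    """Transformer over SPT tokens of a CPD map, with class-token readout."""

    def __init__(self, cfg: TTMConfig, image_shape: tuple[int, int],
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.image_shape = tuple(image_shape)
        p = cfg.patch_size
        hp = self.image_shape[0] + (-self.image_shape[0]) % p
        wp = self.image_shape[1] + (-self.image_shape[1]) % p
        self.padded_shape = (hp, wp)
        self.n_tokens = (hp // p) * (wp // p)
        patch_dim = p * p * (1 + len(cfg.shift_set))
        self.token_norm = LayerNorm(patch_dim)
        self.token_proj = Linear(patch_dim, cfg.embed_dim, rng)
        self.cls_token = parameter(rng.normal(0.0, 0.02, (1, 1, cfg.embed_dim)))
        self.pos_embed = parameter(
            rng.normal(0.0, 0.02, (1, self.n_tokens + 1, cfg.embed_dim)))
        self.blocks = [EncoderBlock(cfg.embed_dim, cfg.n_heads, cfg.mlp_ratio,
                                    rng, cfg.mask_diagonal)
                       for _ in range(cfg.depth)]
        self.norm = LayerNorm(cfg.embed_dim)
        self.head = Linear(cfg.embed_dim, cfg.n_classes, rng)

    def __call__(self, images: np.ndarray) -> TTMOutput:
        images = np.asarray(images, dtype=np.float64)
        squeeze = images.ndim == 2
        if squeeze:
            images = images[None]
        if images.shape[-2:] != self.image_shape:
            raise ValueError(f"expected images of shape {self.image_shape}, "
                             f"got {images.shape[-2:]}")
        padded = pad_to_multiple(images, self.cfg.patch_size)
        patches = shifted_patch_tokenize(padded, self.cfg.patch_size,
                                         self.cfg.shift_set)
        x = self.token_proj(self.token_norm(Tensor(patches)))
        b = x.shape[0]
        cls = self.cls_token + Tensor(np.zeros((b, 1, self.cfg.embed_dim)))
        x = concat([cls, x], axis=1) + self.pos_embed
        for block in self.blocks:
            x = block(x)
        x = self.norm(x)
        features = x[:, 0, :]
        return TTMOutput(features=features, logits=self.head(features))


def ttm_forward(model: TTM, cpd_values: np.ndarray) -> TTMOutput:
    """Run the extractor on one map or a batch of maps (inference or training)."""
    return model(cpd_values)
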