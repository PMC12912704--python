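"""Noise-prediction network: time embedding, cross-covariance attention
blocks with local patch interaction and feed-forward sublayers.

Cross-covariance attention (XCA) transposes the usual attention axes: the
attention map is computed between feature channels, ``A = softmax_cols(
K^T Q / sqrt(d_k))`` with shape (features × features), and the output is
``V A``.  Along the gene axis this captures gene-gene co-expression
structure directly, instead of cell-cell similarity as in standard
self-attention (kept here as the ablation fallback).

Each block applies, with pre-normalization and residual connections:

    h <- h + W_O concat_i XCA(LN(h) W_i^Q, cond W_i^K, cond W_i^V)
    h <- h + LPI(LN(h))          # depthwise local mixing, window 3
    h <- h + FFN(LN(h))          # position-wise 2-layer MLP

where ``cond`` is the encoded condition lifted to model width plus a
sinusoidal-MLP embedding of the timestep, broadcast to every cell row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor


def sinusoidal_time_encoding(t: int, width: int) -> np.ndarray:
    """Classic sin/cos position encoding of the timestep at `width` dims."""
    if width % 2 != 0:
        raise ValueError("time-embedding width must be even")
    if t < 1:
        raise ValueError("timestep must be >= 1")
    half = width // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / half)
    ang = t * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


def embed_time(t: int, width: int, params: "DenoiserParams | None" = None,
               T: int | None = None):
    """Sinusoidal encoding of t followed by a two-layer MLP (if params given)."""
    if T is not None and t > T:
        raise ValueError(f"timestep {t} exceeds schedule length {T}")
    enc = sinusoidal_time_encoding(t, width)
    if params is None:
        return enc
    e = Tensor(enc[None, :])
    return ad.silu(e @ params.Wt1 + params.bt1) @ params.Wt2 + params.bt2


def xc_attention(Q, K, V, d_k: int) -> Tensor:
    """Feature-axis attention: A = softmax_cols(K^T Q / sqrt(d_k)); out = V A.

    Q, K, V share the cell axis (rows); A has shape (features × features)
    and every column sums to one.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Q, K, V = map(ad._coerce, (Q, K, V))
    A = ad.softmax_axis((K.T @ Q) * (1.0 / np.sqrt(d_k)), axis=0)
    return V @ A


def xc_attention_map(Q, K, d_k: int) -> np.ndarray:
    """The (features × features) column-stochastic attention map itself."""
    Q, K = map(ad._coerce, (Q, K))
    return ad.softmax_axis((K.T @ Q) * (1.0 / np.sqrt(d_k)), axis=0).data


def self_attention_fallback(Q, K, V, d_k: int | None = None) -> Tensor:
    """Standard cell-axis attention softmax_rows(Q K^T / sqrt(d_k)) V.

    Used only under the "w/o XCA" ablation, which swaps the feature-axis
    mechanism for conventional token (cell) attention.
    """
    Q, K, V = map(ad._coerce, (Q, K, V))
    dk = Q.shape[1] if d_k is None else d_k
    if dk <= 0:
        raise ValueError("d_k must be positive")
    A = ad.softmax_axis((Q @ K.T) * (1.0 / np.sqrt(dk)), axis=1)
    return A @ V


def lpi_block(x, params: "LPIParams", window: int | None = None) -> Tensor:
    """Local patch interaction: two depthwise 1-D convolutions (shared odd
    kernel, replicate padding) along the feature axis with a SiLU between,
    plus a residual connection.  Replicate padding keeps constant rows
    constant for normalized kernels."""
    x = ad._coerce(x)
    return x + _lpi_inner(x, params, window=window)


def _lpi_inner(x, params: "LPIParams", window: int | None = None) -> Tensor:
    """The LPI sublayer without its residual (used by the pre-norm stack)."""
    x = ad._coerce(x)
    w = len(params.k1.data) if window is None else window
    if w > x.shape[1]:
        raise ValueError(f"LPI window {w} larger than feature count {x.shape[1]}")
    inner = _depthwise_conv(x, params.k1, params.b1)
    inner = ad.silu(inner)
    return _depthwise_conv(inner, params.k2, params.b2)


def _depthwise_conv(x: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    w = len(kernel.data)
    pad = w // 2
    left = [x[:, :1]] * pad
    right = [x[:, -1:]] * pad
    xp = ad.concat(left + [x] + right, axis=1)
    n = x.shape[1]
    out = None
    for j in range(w):
        term = xp[:, j : j + n] * kernel[j : j + 1]
        out = term if out is None else out + term
    return out + bias


@dataclass
class LPIParams:
    k1: Tensor  # (window,)
    b1: Tensor  # (1,)
    k2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, window: int = 3,
             identity: bool = False) -> "LPIParams":
        k = 1.0 / np.sqrt(window)
        k1 = rng.uniform(-k, k, window)
        # identity: zero the second kernel so the residual path is exact
        k2 = np.zeros(window) if identity else rng.uniform(-k, k, window)
        return cls(
            k1=Tensor(k1, requires_grad=True),
            b1=Tensor(np.zeros(1), requires_grad=True),
            k2=Tensor(k2, requires_grad=True),
            b2=Tensor(np.zeros(1), requires_grad=True),
        )

    def tensors(self):
        return [self.k1, self.b1, self.k2, self.b2]


def _ln_params(width: int) -> tuple[Tensor, Tensor]:
    return (
        Tensor(np.ones((1, width)), requires_grad=True),
        Tensor(np.zeros((1, width)), requires_grad=True),
    )


@dataclass
class BlockParams:
    ln1_g: Tensor
    ln1_b: Tensor
    WQ: Tensor  # (d, d) — columns split across heads
    WK: Tensor
    WV: Tensor
    WO: Tensor  # (d, d)
    bO: Tensor
    ln_lpi_g: Tensor
    ln_lpi_b: Tensor
    lpi: LPIParams
    ln2_g: Tensor
    ln2_b: Tensor
    W1: Tensor  # FFN
    b1: Tensor
    W2: Tensor
    b2: Tensor

    def tensors(self):
        return [
            self.ln1_g, self.ln1_b, self.WQ, self.WK, self.WV, self.WO,
            self.bO, self.ln_lpi_g, self.ln_lpi_b, *self.lpi.tensors(),
            self.ln2_g, self.ln2_b, self.W1, self.b1, self.W2, self.b2,
        ]


@dataclass
class DenoiserParams:
    """All weights of the noise-prediction network."""

    n_genes: int
    width: int
    n_heads: int
    blocks: list[BlockParams]
    W_in: Tensor
    b_in: Tensor
    W_cond: Tensor
    b_cond: Tensor
    Wt1: Tensor
    bt1: Tensor
    Wt2: Tensor
    bt2: Tensor
    ln_f_g: Tensor = None
    ln_f_b: Tensor = None
    W_out: Tensor = None
    b_out: Tensor = None

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @staticmethod
    def default_width(n_genes: int) -> int:
        """Hidden width 1024 above 500 genes, 512 otherwise."""
        return 1024 if n_genes > 500 else 512

    @classmethod
    def init(
        cls,
        n_genes: int,
        width: int | None = None,
        n_blocks: int = 6,
        n_heads: int = 16,
        ffn_mult: int = 2,
        rng: np.random.Generator | None = None,
    ) -> "DenoiserParams":
        rng = rng if rng is not None else np.random.default_rng(0)
        width = cls.default_width(n_genes) if width is None else width
        if width % n_heads != 0:
            raise ValueError(f"width {width} not divisible by n_heads {n_heads}")
        if width % 2 != 0:
            raise ValueError("width must be even for the time embedding")

        def u(fan_in, *shape):
            k = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-k, k, shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        blocks = []
        for _ in range(n_blocks):
            g1, b1 = _ln_params(width)
            gl, bl = _ln_params(width)
            g2, b2 = _ln_params(width)
            blocks.append(
                BlockParams(
                    ln1_g=g1, ln1_b=b1,
                    WQ=u(width, width, width),
                    WK=u(width, width, width),
                    WV=u(width, width, width),
                    WO=u(width, width, width),
                    bO=zeros(1, width),
                    ln_lpi_g=gl, ln_lpi_b=bl,
                    lpi=LPIParams.init(rng),
                    ln2_g=g2, ln2_b=b2,
                    W1=u(width, width, ffn_mult * width),
                    b1=zeros(1, ffn_mult * width),
                    W2=u(ffn_mult * width, ffn_mult * width, width),
                    b2=zeros(1, width),
                )
            )
        gf, bf = _ln_params(width)
        return cls(
            n_genes=n_genes,
            width=width,
            n_heads=n_heads,
            blocks=blocks,
            W_in=u(n_genes, n_genes, width),
            b_in=zeros(1, width),
            W_cond=u(n_genes, n_genes, width),
            b_cond=zeros(1, width),
            Wt1=u(width, width, width),
            bt1=zeros(1, width),
            Wt2=u(width, width, width),
            bt2=zeros(1, width),
            ln_f_g=gf,
            ln_f_b=bf,
            W_out=u(width, width, n_genes),
            b_out=zeros(1, n_genes),
        )

    def tensors(self) -> list[Tensor]:
        ts = [
            self.W_in, self.b_in, self.W_cond, self.b_cond,
            self.Wt1, self.bt1, self.Wt2, self.bt2,
            self.ln_f_g, self.ln_f_b, self.W_out, self.b_out,
        ]
        for b in self.blocks:
            ts += b.tensors()
        return ts


def denoiser_forward(
    x_in,
    cond_gene_width,
    t: int,
    params: DenoiserParams,
    use_self_attention: bool = False,
    T: int | None = None,
) -> Tensor:
    """Predict the noise in `x_in` (cells × genes) given the condition.

    `cond_gene_width` is the encoded condition already reconciled to gene
    width (the raw masked conditional under the "w/o BiLSTM" ablation).
    `use_self_attention=True` swaps XCA for cell-axis attention ("w/o XCA").
    """
    x_in = ad._coerce(x_in)
    cond = ad._coerce(cond_gene_width)
    if x_in.shape[1] != params.n_genes or cond.shape != x_in.shape:
        raise ValueError(
            f"expected (cells, {params.n_genes}) inputs, got {x_in.shape} and {cond.shape}"
        )
    d, H = params.width, params.n_heads
    dh = d // H
    t_emb = embed_time(t, d, params, T=T)
    c_emb = (cond @ params.W_cond + params.b_cond) + t_emb  # broadcast over cells
    h = x_in @ params.W_in + params.b_in
    for blk in params.blocks:
        hn = ad.layer_norm(h, blk.ln1_g, blk.ln1_b)
        Qs = hn @ blk.WQ
        Ks = c_emb @ blk.WK
        Vs = c_emb @ blk.WV
        heads = []
        for i in range(H):
            sl = slice(i * dh, (i + 1) * dh)
            Q, K, V = Qs[:, sl], Ks[:, sl], Vs[:, sl]
            if use_self_attention:
                heads.append(self_attention_fallback(Q, K, V, dh))
            else:
                heads.append(xc_attention(Q, K, V, dh))
        attn = ad.concat(heads, axis=1) @ blk.WO + blk.bO
        h = h + attn
        h = h + _lpi_inner(ad.layer_norm(h, blk.ln_lpi_g, blk.ln_lpi_b), blk.lpi)
        hn2 = ad.layer_norm(h, blk.ln2_g, blk.ln2_b)
        h = h + ad.silu(hn2 @ blk.W1 + blk.b1) @ blk.W2 + blk.b2
    out = ad.layer_norm(h, params.ln_f_g, params.ln_f_b) @ params.W_out + params.b_out
    return out
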