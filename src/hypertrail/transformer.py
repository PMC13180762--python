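"""Time-aware masked hyperedge attention.

A trail of tokenized hyperedges (oldest first, candidate last) is run
through a causally masked transformer encoder: scaled dot-product attention
in which each position may attend only to itself and earlier positions, so
the contextualized embedding ``h^{(k)}`` of a hyperedge summarises the
history up to step k without leaking future information.  A sigmoid-gated
position-wise MLP then maps each contextualized embedding to a prediction
score in (0, 1).

The attention scale is ``sqrt(d_token)`` (shared across heads), matching
the formulation this implements rather than the per-head convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttentionBlockParams",
    "ScorerParams",
    "NEG_INF",
    "causal_mask",
    "masked_attention",
    "encoder_block",
    "score",
]

NEG_INF = -1e9  # additive-mask sentinel; large enough that softmax weight is 0


@dataclass
class AttentionBlockParams:
    """One post-norm transformer encoder block.

    ``WQ``/``WK``/``WV`` are (d_token, d_token); columns are split evenly
    across ``n_heads`` heads (d_head = d_token // n_heads).  ``WO`` projects
    the concatenated heads back to d_token.  The feed-forward sublayer is a
    two-layer ReLU network of width ``ffn_width``; both sublayers use
    residual connections followed by layer normalisation.
    """

    WQ: Tensor
    WK: Tensor
    WV: Tensor
    WO: Tensor
    ff_W1: Tensor
    ff_b1: Tensor
    ff_W2: Tensor
    ff_b2: Tensor
    ln1_gamma: Tensor
    ln1_beta: Tensor
    ln2_gamma: Tensor
    ln2_beta: Tensor
    n_heads: int

    @classmethod
    def init(cls, d_token: int, n_heads: int, ffn_width: int | None = None,
             rng: np.random.Generator | None = None) -> "AttentionBlockParams":
        if d_token % n_heads != 0:
            raise ValueError(f"d_token={d_token} not divisible by n_heads={n_heads}")
        rng = rng or np.random.default_rng(0)
        ffn_width = ffn_width or d_token
        s = 1.0 / np.sqrt(d_token)
        mk = lambda *shape: Tensor(rng.normal(0.0, s, size=shape), requires_grad=True)
        return cls(
            WQ=mk(d_token, d_token), WK=mk(d_token, d_token), WV=mk(d_token, d_token),
            WO=mk(d_token, d_token),
            ff_W1=mk(d_token, ffn_width), ff_b1=Tensor(np.zeros((1, ffn_width)), requires_grad=True),
            ff_W2=mk(ffn_width, d_token), ff_b2=Tensor(np.zeros((1, d_token)), requires_grad=True),
            ln1_gamma=Tensor(np.ones((1, d_token)), requires_grad=True),
            ln1_beta=Tensor(np.zeros((1, d_token)), requires_grad=True),
            ln2_gamma=Tensor(np.ones((1, d_token)), requires_grad=True),
            ln2_beta=Tensor(np.zeros((1, d_token)), requires_grad=True),
            n_heads=n_heads,
        )

    def parameters(self) -> list[Tensor]:
        return [self.WQ, self.WK, self.WV, self.WO,
                self.ff_W1, self.ff_b1, self.ff_W2, self.ff_b2,
                self.ln1_gamma, self.ln1_beta, self.ln2_gamma, self.ln2_beta]


@dataclass
class ScorerParams:
    """Two-layer position-wise MLP with a final sigmoid gate."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor

    @classmethod
    def init(cls, d_token: int, hidden: int | None = None,
             rng: np.random.Generator | None = None) -> "ScorerParams":
        rng = rng or np.random.default_rng(0)
        hidden = hidden or d_token
        s = 1.0 / np.sqrt(d_token)
        return cls(
            W1=Tensor(rng.normal(0.0, s, size=(d_token, hidden)), requires_grad=True),
            b1=Tensor(np.zeros((1, hidden)), requires_grad=True),
            W2=Tensor(rng.normal(0.0, s, size=(hidden, 1)), requires_grad=True),
            b2=Tensor(np.zeros((1, 1)), requires_grad=True),
        )

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def causal_mask(n: int) -> np.ndarray:
    """Additive mask M: 0 at (a, b) for b <= a, a large negative sentinel on
    strictly-upper-triangular entries so no position attends to the future."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    M = np.zeros((n, n), dtype=float)
    M[np.triu_indices(n, k=1)] = NEG_INF
    return M


def masked_attention(Z: Tensor, params: AttentionBlockParams, M: np.ndarray) -> list[Tensor]:
    """Per-head masked scaled dot-product attention:
    softmax((Q K^T + M) / sqrt(d_token)) V.  Returns one (n, d_head) Tensor
    per head."""
    n, d_token = Z.shape
    if M.shape != (n, n):
        raise ValueError(f"mask shape {M.shape} does not match sequence length {n}")
    H = params.n_heads
    d_head = d_token // H
    Q = Z @ params.WQ
    K = Z @ params.WK
    V = Z @ params.WV
    scale = 1.0 / np.sqrt(d_token)
    heads = []
    for h in range(H):
        sl = slice(h * d_head, (h + 1) * d_head)
        Qh, Kh, Vh = Q[:, sl], K[:, sl], V[:, sl]
        logits = (Qh @ Kh.T + Tensor(M)) * scale
        weights = ad.softmax(logits, axis=-1)
        heads.append(weights @ Vh)
    return heads


def encoder_block(Z: Tensor, params: AttentionBlockParams,
                  M: np.ndarray | None = None) -> Tensor:
    """One post-norm encoder block over a token matrix Z (n, d_token):
    multi-head masked attention -> W_O -> residual + layer norm ->
    feed-forward -> residual + layer norm.  Causality is preserved end to
    end because all sublayers besides attention act position-wise."""
    n = Z.shape[0]
    if M is None:
        M = causal_mask(n)
    heads = masked_attention(Z, params, M)
    attn = ad.concat(heads, axis=1) @ params.WO
    x = ad.layer_norm(Z + attn, params.ln1_gamma, params.ln1_beta)
    ff = ad.relu(x @ params.ff_W1 + params.ff_b1) @ params.ff_W2 + params.ff_b2
    return ad.layer_norm(x + ff, params.ln2_gamma, params.ln2_beta)


def score(Hseq: Tensor, mlp: ScorerParams) -> Tensor:
    """Position-wise sigmoid-gated MLP mapping contextualized embeddings to
    prediction scores; returns an (n, 1) Tensor with entries in (0, 1)."""
    hidden = ad.relu(Hseq @ mlp.W1 + mlp.b1)
    return ad.sigmoid(hidden @ mlp.W2 + mlp.b2)
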