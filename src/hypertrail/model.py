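"""Full hyperedge-prediction model: learnable concept features initialised
from random-walk positional encodings, a local hypergraph convolution, a
cosine time encoder, stacked causally masked attention blocks, and a
sigmoid-gated scorer.

The model scores a *sequence* — a trail of predecessor hyperedges followed
by the candidate — and exposes the two forward modes training and
evaluation need:

* :meth:`HyperedgePredictor.forward_sequence` runs the positive pass and
  returns contextualized embeddings and scores for every position;
* :meth:`HyperedgePredictor.forward_substituted` re-runs with a negative
  hyperedge substituted at one position, reusing the positive prefix tokens
  (exact under the causal mask) and reading only the substituted position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import encoders as enc
from . import transformer as tfm
from .hypergraph import Hyperedge, TemporalHypergraph, incidence

__all__ = ["ModelConfig", "HyperedgePredictor"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters; the walk length L = 5 is the only one
    fixed by the method, the rest are desk-scale defaults."""

    d: int = 32
    d_time: int = 8
    walk_length: int = enc.DEFAULT_WALK_LENGTH
    hcn_layers: int = 1
    hcn_nonlinearity: str = "relu"
    hcn_incident_reduce: str = "sum"
    n_heads: int = 2
    n_blocks: int = 1
    ffn_width: int | None = 64
    scorer_hidden: int | None = 64
    pe_graph_scope: str = "train_only"  # or "full"

    @property
    def d_token(self) -> int:
        return self.d + self.d_time


class HyperedgePredictor:
    """All learnable parameters theta plus the forward computation."""

    def __init__(self, config: ModelConfig, pe_table: np.ndarray,
                 rng: np.random.Generator):
        cfg = config
        self.config = cfg
        x0 = enc.init_concept_features(
            enc.PositionalEncodings(pe_table, cfg.walk_length), cfg.d)
        self.features = Tensor(x0, requires_grad=True)
        self.hcn = enc.LocalHCNParams.init(
            cfg.d, cfg.hcn_layers, cfg.hcn_nonlinearity, rng,
            incident_reduce=cfg.hcn_incident_reduce)
        self.time_encoder = enc.TimeEncoder.init(cfg.d_time, rng)
        self.blocks = [
            tfm.AttentionBlockParams.init(cfg.d_token, cfg.n_heads, cfg.ffn_width, rng)
            for _ in range(cfg.n_blocks)
        ]
        self.scorer = tfm.ScorerParams.init(cfg.d_token, cfg.scorer_hidden, rng)

    # -- construction ---------------------------------------------------------
    @classmethod
    def build(cls, th: TemporalHypergraph, config: ModelConfig,
              seed: int = 0, pe_edges: list[Hyperedge] | None = None) -> "HyperedgePredictor":
        """Create a model whose positional encodings are computed on
        ``pe_edges`` (by default the training-period hypergraph should be
        passed here to avoid structural leakage from future periods).

        Concepts with zero degree among ``pe_edges`` receive all-zero
        positional encodings rather than failing the bipartite expansion:
        they still get learnable features, only their walk-based prior is
        uninformative.
        """
        rng = np.random.default_rng(seed)
        edges = pe_edges if pe_edges is not None else list(th.hyperedges())
        H = incidence(edges, th.vocabulary)
        deg = H.entries.sum(axis=1)
        active = np.flatnonzero(deg > 0)
        pe_table = np.zeros((th.vocabulary.size, config.walk_length))
        if len(active) and len(edges):
            sub = H.entries[active, :]
            keep_cols = np.flatnonzero(sub.sum(axis=0) > 0)
            sub = sub[:, keep_cols]
            from .hypergraph import IncidenceMatrix
            B = enc.bipartite_expand(IncidenceMatrix(sub, {}))
            pe = enc.rw_positional_encodings(B, config.walk_length)
            pe_table[active, :] = pe.table
        return cls(config, pe_table, rng)

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = [self.features]
        params += self.hcn.parameters()
        params += self.time_encoder.parameters()
        for block in self.blocks:
            params += block.parameters()
        params += self.scorer.parameters()
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = np.array(a, dtype=np.float64)

    # -- forward --------------------------------------------------------------
    def tokens_for(self, edges: list[Hyperedge], times: list[int]) -> list[Tensor]:
        """Tokenize a local hypergraph: one shared convolution over all
        ``edges``, then per-edge concatenation with its time encoding."""
        z = enc.local_hcn_matrix(edges, self.features, self.hcn)
        return [
            enc.tokenize(z[i].reshape(1, -1), enc.time_encode(t, self.time_encoder))
            for i, t in enumerate(times)
        ]

    def _transform(self, tokens: list[Tensor]) -> tuple[Tensor, Tensor]:
        Z = tokens[0] if len(tokens) == 1 else ad.concat(tokens, axis=0)
        M = tfm.causal_mask(Z.shape[0])
        H = Z
        for block in self.blocks:
            H = tfm.encoder_block(H, block, M)
        s = tfm.score(H, self.scorer)
        return H, s

    def forward_sequence(self, edges: list[Hyperedge], times: list[int] | None = None
                         ) -> tuple[Tensor, Tensor, list[Tensor]]:
        """Positive pass over a trail-plus-candidate sequence.

        Returns (Hseq, scores, tokens): contextualized embeddings (n,
        d_token), scores (n, 1), and the token list for prefix reuse in
        negative passes.
        """
        if times is None:
            times = [e.timestamp for e in edges]
        tokens = self.tokens_for(edges, times)
        H, s = self._transform(tokens)
        return H, s, tokens

    def forward_substituted(self, edges: list[Hyperedge], times: list[int],
                            pos_tokens: list[Tensor], k: int,
                            negative: Hyperedge, neg_time: int | None = None
                            ) -> tuple[Tensor, Tensor]:
        """Negative pass: substitute ``negative`` for the position-k
        hyperedge, recompute its embedding on the substituted local
        hypergraph, splice the new token into the positive prefix, and run
        the transformer on positions 0..k only (bit-equivalent to the full
        sequence under the causal mask).  Returns (h_k, s_k) for the
        substituted position.
        """
        sub_edges = list(edges)
        sub_edges[k] = negative
        t_neg = negative.timestamp if neg_time is None else neg_time
        z = enc.local_hcn_matrix(sub_edges, self.features, self.hcn)
        token = enc.tokenize(z[k].reshape(1, -1), enc.time_encode(t_neg, self.time_encoder))
        seq = pos_tokens[:k] + [token]
        H, s = self._transform(seq)
        return H[k].reshape(1, -1), s[k].reshape(1, 1)

    def score_pair(self, trail_edges: list[Hyperedge], candidate: Hyperedge,
                   candidate_time: int | None = None) -> float:
        """Convenience: probability score of ``candidate`` given its trail."""
        edges = trail_edges + [candidate]
        times = [e.timestamp for e in trail_edges] + [
            candidate.timestamp if candidate_time is None else candidate_time]
        _, s, _ = self.forward_sequence(edges, times)
        return float(s.data[-1, 0])
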