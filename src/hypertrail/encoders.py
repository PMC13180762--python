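"""Hyperedge tokenization: global random-walk positional encodings,
learnable concept features, local hypergraph convolution, and time encoding.

Each hyperedge in a trail is turned into a token carrying three signals:

* **global awareness** — concept features are initialised from random-walk
  return probabilities on the hypergraph's bipartite expansion (the graph
  with one vertex per concept and per hyperedge, edges for membership);
* **local awareness** — a hypergraph convolution restricted to the trail
  plus the candidate hyperedge produces an embedding ``z_i`` per hyperedge
  (phi_1 aggregates member features into ``h_i``, phi_2 updates node
  features, the readout averages updated member features);
* **temporal context** — a learnable cosine time encoding
  ``psi(t) = cos(W t + b)`` is concatenated, giving a token of length
  ``d_token = d + d_time``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .hypergraph import Hyperedge, IncidenceMatrix

__all__ = [
    "BipartiteWalkMatrix",
    "PositionalEncodings",
    "LocalHCNParams",
    "TimeEncoder",
    "bipartite_expand",
    "rw_positional_encodings",
    "init_concept_features",
    "local_hcn",
    "local_hcn_matrix",
    "time_encode",
    "tokenize",
]

DEFAULT_WALK_LENGTH = 5  # return-probability walk length L


@dataclass
class BipartiteWalkMatrix:
    """Row-stochastic transition matrix of the bipartite expansion.

    Block layout: concepts occupy rows/columns ``0..N-1``, hyperedges
    ``N..N+M-1``; diagonal blocks are zero, off-diagonal blocks hold the
    incidence matrix and its transpose, each row normalised by its degree.
    """

    matrix: np.ndarray
    n_concepts: int
    n_hyperedges: int


@dataclass
class PositionalEncodings:
    """Table PE (N x L): entry (j, l-1) is the probability that a random
    walk starting at concept j returns to j in l steps.  Odd-step entries
    are exactly zero because the expansion is bipartite."""

    table: np.ndarray
    walk_length: int


_NONLINEARITIES: dict[str, Callable[[Tensor], Tensor]] = {
    "tanh": ad.tanh,
    "relu": ad.relu,
    "identity": lambda x: x,
}


@dataclass
class LocalHCNParams:
    """Weights of the local hypergraph convolution.

    One layer computes, over the local hypergraph only:
    ``h_i = mean_{j in e_i} x_j``,
    ``x~_j = act(x_j A1 + reduce_{e_i in E_j} h_i A2)``, and the readout
    ``z_i = mean_{j in e_i} x~_j``.  ``A1``/``A2`` are lists with one
    (d, d) matrix per layer.

    ``incident_reduce`` selects the phi_2 reducer over a concept's incident
    hyperedge messages.  ``sum`` (default) keeps each concept's local degree
    visible — a concept shared between the candidate and its trail
    accumulates more message mass than a concept appearing nowhere else,
    which is precisely the overlap signal hard-negative discrimination
    needs; ``mean`` normalises it away and is kept for ablation.
    """

    A1: list[Tensor]
    A2: list[Tensor]
    nonlinearity: str = "tanh"
    incident_reduce: str = "sum"

    @property
    def n_layers(self) -> int:
        return len(self.A1)

    @classmethod
    def init(cls, d: int, n_layers: int = 1, nonlinearity: str = "tanh",
             rng: np.random.Generator | None = None,
             incident_reduce: str = "sum") -> "LocalHCNParams":
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(d)
        mk = lambda: Tensor(rng.normal(0.0, scale, size=(d, d)), requires_grad=True)
        return cls(A1=[mk() for _ in range(n_layers)],
                   A2=[mk() for _ in range(n_layers)],
                   nonlinearity=nonlinearity,
                   incident_reduce=incident_reduce)

    def parameters(self) -> list[Tensor]:
        return [*self.A1, *self.A2]


@dataclass
class TimeEncoder:
    """Learnable cosine time encoding psi(t) = cos(W t + b) with
    W in R^{d_time} and scalar b broadcast across components."""

    W: Tensor
    b: Tensor

    @classmethod
    def init(cls, d_time: int, rng: np.random.Generator | None = None) -> "TimeEncoder":
        rng = rng or np.random.default_rng(0)
        # geometric-ish frequency spread keeps nearby years distinguishable
        w0 = 1.0 / np.power(10.0, np.linspace(0, 1.5, d_time))
        w0 = w0 * (1.0 + 0.01 * rng.standard_normal(d_time))
        return cls(W=Tensor(w0.reshape(1, -1), requires_grad=True),
                   b=Tensor(np.zeros((1, 1)), requires_grad=True))

    @property
    def d_time(self) -> int:
        return self.W.shape[1]

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def bipartite_expand(H: IncidenceMatrix) -> BipartiteWalkMatrix:
    """Expand incidence matrix H into the row-stochastic bipartite walk
    matrix B = [[0, H], [H^T, 0]] with every row divided by its degree."""
    entries = H.entries
    n, m = entries.shape
    col_deg = entries.sum(axis=0)
    row_deg = entries.sum(axis=1)
    if m and np.any(col_deg == 0):
        raise ValueError("empty hyperedge column; filter degenerate hyperedges upstream")
    if n and np.any(row_deg == 0):
        bad = int(np.flatnonzero(row_deg == 0)[0])
        raise ValueError(
            f"concept {bad} has zero degree; compact the vocabulary upstream "
            "(filter_by_size with compact_vocabulary=True)"
        )
    B = np.zeros((n + m, n + m), dtype=float)
    B[:n, n:] = entries / row_deg[:, None]
    B[n:, :n] = entries.T / col_deg[:, None]
    return BipartiteWalkMatrix(matrix=B, n_concepts=n, n_hyperedges=m)


def rw_positional_encodings(B: BipartiteWalkMatrix, L: int = DEFAULT_WALK_LENGTH) -> PositionalEncodings:
    """Collect l-step return probabilities (diagonal of B^l) for each concept
    and l = 1..L, by iterated multiplication B^l = B^{l-1} B."""
    if L < 1:
        raise ValueError("walk length L must be >= 1")
    n = B.n_concepts
    table = np.zeros((n, L), dtype=float)
    power = B.matrix
    table[:, 0] = np.diag(power)[:n]
    for l in range(1, L):
        power = power @ B.matrix
        table[:, l] = np.diag(power)[:n]
    return PositionalEncodings(table=table, walk_length=L)


def init_concept_features(PE: PositionalEncodings, d: int) -> np.ndarray:
    """Initial concept feature table: the L positional-encoding columns
    padded with zeros up to dimension d.  The caller wraps the result in a
    trainable Tensor."""
    L = PE.walk_length
    if d < L:
        raise ValueError(f"feature dimension d={d} must be >= walk length L={L}")
    n = PE.table.shape[0]
    x = np.zeros((n, d), dtype=float)
    x[:, :L] = PE.table
    return x


def local_hcn_matrix(
    local_edges: Sequence[Hyperedge],
    features: Tensor,
    params: LocalHCNParams,
) -> Tensor:
    """Hypergraph convolution over a local hypergraph; returns the (m, d)
    matrix of hyperedge embeddings, row i for ``local_edges[i]``."""
    if not local_edges:
        raise ValueError("local hypergraph is empty")
    act = _NONLINEARITIES[params.nonlinearity]
    concepts = sorted({j for e in local_edges for j in e.members})
    n_f = features.shape[0]
    for j in concepts:
        if j >= n_f:
            raise ValueError(f"member {j} absent from feature table of size {n_f}")
    pos = {j: i for i, j in enumerate(concepts)}
    n, m = len(concepts), len(local_edges)
    H = np.zeros((n, m), dtype=float)
    for i, e in enumerate(local_edges):
        for j in e.members:
            H[pos[j], i] = 1.0
    mean_members = (H / H.sum(axis=0, keepdims=True)).T  # (m, n): phi_1 / readout
    if params.incident_reduce == "sum":
        incident = H  # (n, m): phi_2 accumulates incident-edge messages
    elif params.incident_reduce == "mean":
        incident = H / H.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown incident_reduce {params.incident_reduce!r}")

    x = ad.take_rows(features, concepts)  # (n, d)
    for A1, A2 in zip(params.A1, params.A2):
        h = Tensor(mean_members) @ x                      # (m, d) hyperedge messages
        agg = Tensor(incident) @ h                        # (n, d) back to nodes
        x = act(x @ A1 + agg @ A2)
    return Tensor(mean_members) @ x                       # (m, d) readout


def local_hcn(
    local_edges: Sequence[Hyperedge],
    features: Tensor,
    params: LocalHCNParams,
) -> dict[int, Tensor]:
    """Hypergraph convolution restricted to the local hypergraph formed by a
    trail plus the candidate hyperedge being scored.

    Returns a map hyperedge id -> embedding ``z_i`` (a (1, d) Tensor).  The
    computation is permutation invariant in the members and in the order of
    ``local_edges``.
    """
    z = local_hcn_matrix(local_edges, features, params)
    return {e.id: z[i].reshape(1, -1) for i, e in enumerate(local_edges)}


def time_encode(t: int | float, enc: TimeEncoder) -> Tensor:
    """psi(t) = cos(W t + b), a (1, d_time) Tensor with entries in [-1, 1].
    ``t`` is the 0-based remapped time index."""
    if t < 0:
        raise ValueError("time index must be >= 0")
    return ad.cos(enc.W * float(t) + enc.b)


def tokenize(z: Tensor, psi: Tensor) -> Tensor:
    """Concatenate a hyperedge embedding with its time encoding:
    token = Concat(z, psi(t)), length d + d_time, z occupying the prefix."""
    if z.ndim != 2 or psi.ndim != 2 or z.shape[0] != 1 or psi.shape[0] != 1:
        raise ValueError("tokenize expects (1, d) and (1, d_time) inputs")
    return ad.concat([z, psi], axis=1)
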