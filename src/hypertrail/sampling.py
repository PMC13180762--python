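"""Negative sampling and trail-of-ideas generation.

Hard negatives corrupt a real hyperedge by replacing a fraction ``r`` of
its concepts with era-plausible substitutes, producing deceptively similar
fakes; global negatives are drawn uniformly from the whole hypergraph and
represent unrelated hypotheses.  Trails of ideas are temporally
constrained random walks backwards in time over concept-overlapping
hyperedges, approximating how a hypothesis builds on its predecessors.
``build_instances`` assembles trails with per-position negatives into the
training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hypergraph import DatasetSplits, Hyperedge, TemporalHypergraph, subgraph

__all__ = [
    "SamplerConfig",
    "Trail",
    "TrainingInstance",
    "hard_negative",
    "global_negative",
    "trail",
    "build_instances",
]

# hard/global negatives get ids in a disjoint range so they can never
# collide with real hyperedge ids inside a local hypergraph
_NEGATIVE_ID_BASE = 10 ** 9


@dataclass
class SamplerConfig:
    """Knobs of the negative sampler and the trail walk.

    ``r`` is the replacement rate of hard negatives (default 0.2, i.e. 20%
    of a hyperedge's concepts are replaced).  ``predecessor_policy``
    selects the backward-walk distribution: ``overlap_weighted`` follows
    the preferential-attachment reading (probability proportional to
    concept overlap), ``uniform`` treats all qualifying predecessors
    equally.  ``allow_gap_skip`` lets the walk search further back, one
    step at a time, when a time step has no overlapping hyperedge.
    """

    r: float = 0.2
    predecessor_policy: str = "overlap_weighted"
    per_step_negatives: bool = True
    allow_gap_skip: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"replacement rate r={self.r} outside [0, 1]")
        if self.predecessor_policy not in ("overlap_weighted", "uniform"):
            raise ValueError(f"unknown predecessor_policy {self.predecessor_policy!r}")


@dataclass
class Trail:
    """Temporally ordered predecessors of a target hyperedge.

    ``predecessors`` is oldest-first with strictly increasing timestamps,
    each consecutive pair (including the last predecessor and the target)
    sharing at least one concept.  It may be empty.
    """

    target: Hyperedge
    predecessors: list[Hyperedge] = field(default_factory=list)

    @property
    def sequence(self) -> list[Hyperedge]:
        """Trail plus target, the transformer's input order."""
        return [*self.predecessors, self.target]

    def __len__(self) -> int:
        return len(self.predecessors)

    def validate(self) -> None:
        chain = self.sequence
        for a, b in zip(chain, chain[1:]):
            if a.timestamp >= b.timestamp:
                raise ValueError("trail timestamps must strictly increase")
            if not (a.members & b.members):
                raise ValueError("consecutive trail hyperedges must overlap")


@dataclass
class TrainingInstance:
    """A trail plus per-scored-position hard and global negatives.

    ``scored_positions`` indexes into ``trail.sequence``; ``hard_negatives``
    and ``global_negatives`` align with it.
    """

    trail: Trail
    scored_positions: list[int]
    hard_negatives: list[Hyperedge]
    global_negatives: list[Hyperedge]

    def __post_init__(self) -> None:
        if not (len(self.scored_positions) == len(self.hard_negatives)
                == len(self.global_negatives)):
            raise ValueError("negatives must align with scored positions")


def hard_negative(
    e: Hyperedge,
    r: float,
    candidate_vocab: set[int] | frozenset[int],
    rng: np.random.Generator,
    negative_id: int | None = None,
) -> Hyperedge:
    """Corrupt ``e`` by replacing exactly ``k = ceil(r * |e|)`` of its
    concepts (k = 0 only when r = 0) with uniform draws, without
    replacement, from ``candidate_vocab`` minus the current members.  Size
    and timestamp are preserved."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"replacement rate r={r} outside [0, 1]")
    k = math.ceil(r * e.size)
    if k == 0:
        return e
    pool = sorted(set(candidate_vocab) - e.members)
    if len(pool) < k:
        raise ValueError(
            f"need {k} replacement concepts but only {len(pool)} candidates "
            f"outside hyperedge {e.id}")
    removed = rng.choice(sorted(e.members), size=k, replace=False)
    added = rng.choice(pool, size=k, replace=False)
    members = (e.members - set(int(x) for x in removed)) | {int(x) for x in added}
    nid = negative_id if negative_id is not None else _NEGATIVE_ID_BASE + e.id
    return Hyperedge(id=nid, timestamp=e.timestamp, members=frozenset(members),
                     source_id=None)


def global_negative(
    th: TemporalHypergraph,
    exclude_id: int,
    rng: np.random.Generator,
) -> Hyperedge:
    """Draw a hyperedge uniformly from the entire hypergraph, excluding the
    hyperedge with id ``exclude_id``; it can come from any time step."""
    pool = [e for e in th.hyperedges() if e.id != exclude_id]
    if not pool:
        raise ValueError("global negative sampling needs at least 2 hyperedges")
    return pool[int(rng.integers(len(pool)))]


def trail(
    th: TemporalHypergraph,
    target: Hyperedge,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> Trail:
    """Temporally constrained random walk backwards from ``target``.

    At each earlier time step the walk picks a hyperedge sharing at least
    one concept with the *current* hyperedge — with probability
    proportional to the overlap size under ``overlap_weighted``, uniformly
    under ``uniform`` — and recurses until time 0 or no qualifying
    predecessor remains (truncating there unless ``allow_gap_skip`` lets it
    search further back).  The result is stored oldest-first.
    """
    predecessors: list[Hyperedge] = []
    current = target
    t = target.timestamp - 1
    while t >= 0:
        candidates = [e for e in th.snapshots.get(t, [])
                      if e.members & current.members]
        if not candidates:
            if config.allow_gap_skip:
                t -= 1
                continue
            break
        if config.predecessor_policy == "overlap_weighted":
            w = np.array([len(e.members & current.members) for e in candidates],
                         dtype=float)
            probs = w / w.sum()
        else:
            probs = np.full(len(candidates), 1.0 / len(candidates))
        chosen = candidates[int(rng.choice(len(candidates), p=probs))]
        predecessors.append(chosen)
        current = chosen
        t = chosen.timestamp - 1
    predecessors.reverse()
    return Trail(target=target, predecessors=predecessors)


def _period_vocab(th: TemporalHypergraph, t: int) -> set[int]:
    return {j for e in th.snapshots.get(t, []) for j in e.members}


def replacement_candidates(th: TemporalHypergraph, e: Hyperedge,
                           min_pool: int | None = None) -> set[int]:
    """Replacement pool for hard negatives: the same-period vocabulary
    V^(t) when it can supply enough era-plausible substitutes, otherwise
    the global vocabulary."""
    need = min_pool if min_pool is not None else e.size
    pool = _period_vocab(th, e.timestamp)
    if len(pool - e.members) < need:
        pool = set(range(th.vocabulary.size))
    return pool


def build_instances(
    splits: DatasetSplits,
    th: TemporalHypergraph,
    config: SamplerConfig,
    targets: list[Hyperedge] | None = None,
) -> list[TrainingInstance]:
    """Assemble one training instance per target hyperedge (by default the
    training split): its trail drawn from strictly earlier training-period
    hyperedges, plus a hard and a global negative per scored position.

    With ``per_step_negatives`` every position in the trail-plus-target
    sequence is scored; otherwise only the final (target) position.
    Deterministic under ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    targets = splits.train if targets is None else targets
    history = subgraph(th, splits.train)
    instances: list[TrainingInstance] = []
    neg_id = _NEGATIVE_ID_BASE
    for target in targets:
        tr = trail(history, target, config, rng)
        seq = tr.sequence
        positions = list(range(len(seq))) if config.per_step_negatives else [len(seq) - 1]
        hards: list[Hyperedge] = []
        globals_: list[Hyperedge] = []
        for k in positions:
            e = seq[k]
            pool = replacement_candidates(history, e)
            neg_id += 1
            hards.append(hard_negative(e, config.r, pool, rng, negative_id=neg_id))
            globals_.append(global_negative(history, e.id, rng))
        instances.append(TrainingInstance(
            trail=tr, scored_positions=positions,
            hard_negatives=hards, global_negatives=globals_))
    return instances
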