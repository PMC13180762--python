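"""Losses and the training loop.

The objective combines, per scored trail position k:

* a binary cross-entropy term over the positive score, the hard-negative
  score and the global-negative score,
  ``-log s_pos - log(1 - s_hard) - log(1 - s_gns)``;
* a time-anchored contrastive term (skipped at k = 0, where no anchor
  exists) that pulls the positive's contextualized embedding toward the
  previous step's embedding and pushes both negatives beyond a margin:
  ``2*alpha*||h_prev - h_pos||^2
  + (1-alpha) * [ max(0, Margin - ||h_prev - h_hard||_2)^2
                + max(0, Margin - ||h_prev - h_gns||_2)^2 ]``.

The total loss averages the per-instance position sums, the contrastive
part weighted by ``beta``.  Optimisation is plain Adam; everything is
deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import HyperedgePredictor
from .sampling import TrainingInstance

__all__ = [
    "LossConfig",
    "TrainConfig",
    "TrainedModel",
    "Adam",
    "bce_loss",
    "contrastive_loss",
    "instance_loss",
    "train",
]


@dataclass
class LossConfig:
    """alpha balances pull vs push in the contrastive term, Margin is the
    desired separation, beta weights the contrastive loss against the BCE,
    eps clamps log/score arguments."""

    alpha: float = 0.5
    margin: float = 1.0
    beta: float = 0.5
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.margin <= 0 or self.eps <= 0:
            raise ValueError("margin and eps must be positive")


@dataclass
class TrainConfig:
    lr: float = 3e-3
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0
    weight_decay: float = 1e-4
    resample_each_epoch: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainedModel:
    model: HyperedgePredictor
    loss_log: list[float] = field(default_factory=list)


def _as_scalar_tensor(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(float(x))
    return t.reshape(1, 1) if t.data.size == 1 else t


def bce_loss(s_pos, s_hard, s_gns, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy over the positive, hard-negative and
    global-negative scores; each score is clamped to [eps, 1-eps] first."""
    terms = []
    for s, positive in ((s_pos, True), (s_hard, False), (s_gns, False)):
        s = ad.clip(_as_scalar_tensor(s), eps, 1.0 - eps)
        terms.append(-ad.log(s) if positive else -ad.log(1.0 - s))
    return (terms[0] + terms[1] + terms[2]).reshape(1)[0]


def _l2(a: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    """Squared distance and (numerically safe) euclidean distance."""
    diff = (a - b).reshape(1, -1)
    sq = (diff * diff).sum()
    return sq, ad.sqrt(sq + 1e-12)


def contrastive_loss(h_prev, h_pos, h_hard, h_gns,
                     alpha: float = 0.5, margin: float = 1.0) -> Tensor:
    """Time-anchored contrastive loss: pull the positive toward the anchor
    (previous-step contextualized embedding), hinge-push both negatives
    beyond ``margin``; the pull term carries the printed factor 2*alpha."""
    h_prev, h_pos = Tensor._lift(h_prev), Tensor._lift(h_pos)
    h_hard, h_gns = Tensor._lift(h_hard), Tensor._lift(h_gns)
    sq_pos, _ = _l2(h_prev, h_pos)
    pull = 2.0 * alpha * sq_pos
    push = Tensor(0.0)
    for h_neg in (h_hard, h_gns):
        _, dist = _l2(h_prev, h_neg)
        hinge = ad.relu(margin - dist)
        push = push + hinge * hinge
    return pull + (1.0 - alpha) * push


def instance_loss(
    pos_scores: list,
    hard_scores: list,
    gns_scores: list,
    pos_embeddings: list,
    hard_embeddings: list,
    gns_embeddings: list,
    scored_positions: list[int],
    cfg: LossConfig,
) -> Tensor:
    """Inner sum of the training objective for one instance: BCE at every
    scored position plus beta-weighted contrastive loss wherever an anchor
    (the previous position's positive embedding) exists.

    ``pos_scores``/``pos_embeddings`` are indexed by absolute sequence
    position; the negative lists align with ``scored_positions``.
    """
    if not (len(hard_scores) == len(gns_scores) == len(scored_positions)):
        raise ValueError("negative scores must align with scored positions")
    total = Tensor(0.0)
    for i, k in enumerate(scored_positions):
        total = total + bce_loss(pos_scores[k], hard_scores[i], gns_scores[i], cfg.eps)
        if cfg.beta > 0.0 and k > 0:
            cl = contrastive_loss(
                pos_embeddings[k - 1], pos_embeddings[k],
                hard_embeddings[i], gns_embeddings[i],
                alpha=cfg.alpha, margin=cfg.margin)
            total = total + cfg.beta * cl
    return total


class Adam:
    """Standard Adam over a list of Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data


def _forward_instance(model: HyperedgePredictor, inst: TrainingInstance,
                      cfg: LossConfig) -> Tensor:
    """Positive pass plus one substituted pass per (position, negative kind),
    combined into the instance's loss graph."""
    seq = inst.trail.sequence
    times = [e.timestamp for e in seq]
    Hpos, s_pos, tokens = model.forward_sequence(seq, times)
    pos_scores = [s_pos[k].reshape(1, 1) for k in range(len(seq))]
    pos_embs = [Hpos[k].reshape(1, -1) for k in range(len(seq))]
    hard_scores, gns_scores, hard_embs, gns_embs = [], [], [], []
    for i, k in enumerate(inst.scored_positions):
        h_h, s_h = model.forward_substituted(
            seq, times, tokens, k, inst.hard_negatives[i], neg_time=times[k])
        # the global negative keeps its own timestamp: it can be from any step
        h_g, s_g = model.forward_substituted(
            seq, times, tokens, k, inst.global_negatives[i])
        hard_scores.append(s_h)
        gns_scores.append(s_g)
        hard_embs.append(h_h)
        gns_embs.append(h_g)
    return instance_loss(pos_scores, hard_scores, gns_scores,
                         pos_embs, hard_embs, gns_embs,
                         inst.scored_positions, cfg)


def train(
    instances: list[TrainingInstance],
    model: HyperedgePredictor,
    cfg: TrainConfig,
    loss_cfg: LossConfig | None = None,
    instance_factory=None,
    val_fn=None,
) -> TrainedModel:
    """Mini-batch Adam training of the full objective.

    Per epoch the instances are shuffled (seeded), each batch's mean
    instance loss is backpropagated and stepped; the log records the mean
    loss per epoch.  A non-finite loss aborts with a diagnostic.

    ``instance_factory(epoch_seed)``, when given and
    ``cfg.resample_each_epoch`` is set, regenerates trails and negatives
    each epoch (fresh corruptions prevent the model from memorising any
    fixed negative set).  ``val_fn(model) -> float`` (higher is better),
    when given, is evaluated each epoch on the optimisation half of the
    validation period and the best-scoring parameters are restored at the
    end (early stopping).
    """
    if not instances:
        raise ValueError("no training instances")
    loss_cfg = loss_cfg or LossConfig()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    log: list[float] = []
    best_val = -np.inf
    best_state: list[np.ndarray] | None = None
    for epoch in range(cfg.epochs):
        if instance_factory is not None and cfg.resample_each_epoch and epoch > 0:
            instances = instance_factory(int(cfg.seed + 1000 * (epoch + 1)) % (2 ** 31))
        order = rng.permutation(len(instances))
        epoch_losses: list[float] = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [instances[i] for i in order[start:start + cfg.batch_size]]
            opt.zero_grad()
            total = Tensor(0.0)
            for inst in batch:
                total = total + _forward_instance(model, inst, loss_cfg)
            loss = total * (1.0 / len(batch))
            val = float(loss.data)
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss {val} at epoch {epoch}; "
                    "reduce the learning rate or check the data")
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        log.append(float(np.mean(epoch_losses)))
        if val_fn is not None:
            score = float(val_fn(model))
            if score > best_val:
                best_val = score
                best_state = [a.copy() for a in model.state_arrays()]
    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainedModel(model=model, loss_log=log)
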