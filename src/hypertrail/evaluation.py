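"""Metrics and the trail-aware evaluation protocol.

Each held-out target hyperedge is scored against its trail of ideas drawn
from strictly earlier history (train plus the trail half of the validation
period by default); its hard negative is scored at the same final position
with the same trail, giving a balanced 1:1 positive/negative pool over
which AUC, accuracy, precision, F1 and average precision are computed.

Also implemented here: the empirical checks of the two method claims —
that discrimination degrades as the hard-negative replacement rate ``r``
shrinks, and that after contrastive training the positive hyperedge's
embedding sits closer to the temporal anchor than the hard negative's —
plus the cross-dataset consistency (coefficient of variation) and the
ablation-contribution arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm

from .hypergraph import Hyperedge, TemporalHypergraph, subgraph
from .model import HyperedgePredictor
from .sampling import (SamplerConfig, TrainingInstance, hard_negative,
                       global_negative, replacement_candidates, trail)

__all__ = [
    "MetricsReport",
    "ConsistencyReport",
    "compute_metrics",
    "evaluate_model",
    "claim1_curve",
    "claim2_rate",
    "consistency",
    "ablation_contribution",
]


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    precision: float
    f1: float
    average_precision: float
    n_pos: int
    n_neg: int
    threshold: float = 0.5

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "accuracy": self.accuracy,
            "precision": self.precision, "f1": self.f1,
            "average_precision": self.average_precision,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
            "threshold": self.threshold,
        }


@dataclass
class ConsistencyReport:
    values: list[float]
    mean: float
    std: float
    cv_percent: float


def compute_metrics(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """AUC (rank statistic, ties counted half), average precision (step
    rule), and accuracy/precision/F1 at the threshold, with scores >=
    threshold predicted positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: only one class present")
    preds = (scores >= threshold).astype(int)
    return MetricsReport(
        auc=float(skm.roc_auc_score(labels, scores)),
        accuracy=float(skm.accuracy_score(labels, preds)),
        precision=float(skm.precision_score(labels, preds, zero_division=0)),
        f1=float(skm.f1_score(labels, preds, zero_division=0)),
        average_precision=float(skm.average_precision_score(labels, scores)),
        n_pos=int(labels.sum()),
        n_neg=int((1 - labels).sum()),
        threshold=threshold,
    )


def evaluate_model(
    model: HyperedgePredictor,
    eval_targets: list[Hyperedge],
    history_pool: TemporalHypergraph,
    sampler: SamplerConfig,
    negative_kind: str = "hard",
    threshold: float = 0.5,
) -> MetricsReport:
    """Trail-aware 1:1 evaluation.

    For every target: build its trail from ``history_pool`` (which must
    contain only hyperedges strictly earlier than the target), score the
    target at the final position (label 1) and a negative at the same
    position (label 0).  ``negative_kind`` selects hard negatives at the
    sampler's replacement rate, global negatives, or both.  Deterministic
    under ``sampler.rng_seed``.
    """
    if not eval_targets:
        raise ValueError("no evaluation targets")
    if negative_kind not in ("hard", "global", "both"):
        raise ValueError(f"unknown negative_kind {negative_kind!r}")
    rng = np.random.default_rng(sampler.rng_seed)
    scores: list[float] = []
    labels: list[int] = []
    for target in eval_targets:
        for e in history_pool.hyperedges():
            assert e.timestamp < target.timestamp, (
                "history pool leaks a hyperedge at or after the target's time")
        tr = trail(history_pool, target, sampler, rng)
        seq = tr.sequence
        times = [e.timestamp for e in seq]
        _, s, tokens = model.forward_sequence(seq, times)
        scores.append(float(s.data[-1, 0]))
        labels.append(1)
        k = len(seq) - 1
        negs: list[tuple[Hyperedge, int | None]] = []
        if negative_kind in ("hard", "both"):
            pool = replacement_candidates(history_pool, target)
            negs.append((hard_negative(target, sampler.r, pool, rng), times[k]))
        if negative_kind in ("global", "both"):
            negs.append((global_negative(history_pool, target.id, rng), None))
        for neg, neg_time in negs:
            _, s_neg = model.forward_substituted(seq, times, tokens, k, neg,
                                                 neg_time=neg_time)
            scores.append(float(s_neg.data[0, 0]))
            labels.append(0)
    return compute_metrics(scores, labels, threshold)


def _history_before(th: TemporalHypergraph, pool: list[Hyperedge],
                    cutoff: int) -> TemporalHypergraph:
    return subgraph(th, [e for e in pool if e.timestamp < cutoff])


def claim1_curve(
    make_dataset,
    r_values: list[float],
    train_model,
    seeds: list[int] = (0, 1, 2),
) -> dict:
    """Sensitivity of discrimination to the replacement rate ``r``.

    ``make_dataset(seed)`` must return fixed inputs shared across r values;
    ``train_model(dataset, r, seed)`` trains and evaluates one model and
    returns its AUC against hard negatives at that same r.  Reports the
    per-r AUCs and the Spearman rank correlation between r and mean AUC.
    """
    from scipy.stats import spearmanr

    if sorted(r_values) != list(r_values):
        raise ValueError("r_values must be sorted ascending")
    aucs: dict[float, list[float]] = {}
    for r in r_values:
        aucs[r] = [float(train_model(make_dataset(seed), r, seed)) for seed in seeds]
    means = [float(np.mean(aucs[r])) for r in r_values]
    rho = float("nan")
    if len(r_values) > 1:
        rho = float(spearmanr(r_values, means).statistic)
    return {"auc_by_r": aucs, "mean_auc_by_r": dict(zip(r_values, means)),
            "rank_correlation": rho}


def claim2_rate(model: HyperedgePredictor,
                instances: list[TrainingInstance]) -> float:
    """Fraction of instances with a nonempty trail whose positive
    final-position embedding is strictly closer to the previous step's
    anchor embedding than the hard negative's is.  Ties count as failures;
    instances with empty trails are excluded from the denominator."""
    eligible = 0
    closer = 0
    for inst in instances:
        seq = inst.trail.sequence
        if len(seq) < 2:
            continue
        k = len(seq) - 1
        if k not in inst.scored_positions:
            continue
        i = inst.scored_positions.index(k)
        times = [e.timestamp for e in seq]
        Hpos, _, tokens = model.forward_sequence(seq, times)
        h_prev = Hpos.data[k - 1]
        h_pos = Hpos.data[k]
        h_hard, _ = model.forward_substituted(seq, times, tokens, k,
                                              inst.hard_negatives[i],
                                              neg_time=times[k])
        d_pos = float(np.linalg.norm(h_prev - h_pos))
        d_neg = float(np.linalg.norm(h_prev - h_hard.data[0]))
        eligible += 1
        if d_pos < d_neg:
            closer += 1
    if eligible == 0:
        raise ValueError("no instances with nonempty trails")
    return closer / eligible


def consistency(values) -> ConsistencyReport:
    """Cross-dataset consistency: mean, sample (n-1) standard deviation and
    the coefficient of variation CV = 100 * std / mean in percent."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("consistency needs at least 2 values")
    mean = float(np.mean(vals))
    std = float(np.std(vals, ddof=1))
    return ConsistencyReport(values=vals, mean=mean, std=std,
                             cv_percent=100.0 * std / mean)


def ablation_contribution(full: float, ablated: float) -> dict:
    """Absolute and relative contribution of a component: the metric drop
    when it is removed, and that drop as a percentage of full performance."""
    if full == 0:
        raise ValueError("relative contribution undefined for full = 0")
    absolute = full - ablated
    return {"absolute": absolute, "relative_percent": 100.0 * absolute / full}
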