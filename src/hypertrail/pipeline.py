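"""End-to-end convenience wiring: simulate/load -> filter -> split ->
instances -> train -> evaluate.

These helpers encode the retrospective protocol: train on the earliest
period, halve the validation period into an optimisation half and a
trail-history half, hold out the final period for testing, remove val/test
hyperedges whose concept sets already occur in training, and evaluate each
test target against its trail with a 1:1 hard-negative (and optionally
global-negative) pool.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluation import MetricsReport, evaluate_model
from .hypergraph import (DatasetSplits, TemporalHypergraph, filter_by_size,
                         remove_split_leakage, split_by_period, subgraph)
from .model import HyperedgePredictor, ModelConfig
from .sampling import SamplerConfig, build_instances
from .training import LossConfig, TrainConfig, TrainedModel, train

__all__ = ["RunResult", "default_split_years", "prepare_splits", "run_experiment"]


@dataclass
class RunResult:
    """Everything one seeded experiment produced."""

    model: TrainedModel
    splits: DatasetSplits
    metrics_hard: MetricsReport
    metrics_global: MetricsReport | None = None

    def summary(self) -> dict:
        out = {"auc_hard": self.metrics_hard.auc,
               "final_loss": self.model.loss_log[-1] if self.model.loss_log else None,
               "metrics_hard": self.metrics_hard.as_dict()}
        if self.metrics_global is not None:
            out["auc_global"] = self.metrics_global.auc
            out["metrics_global"] = self.metrics_global.as_dict()
        return out


def default_split_years(th: TemporalHypergraph) -> dict[str, tuple[int, int]]:
    """Final year held out for testing, the year before it for validation,
    everything earlier for training (the yearly analogue of the
    train/validation/test periods used on the article-derived data)."""
    years = th.years
    if len(years) < 3:
        raise ValueError("need at least 3 time steps to split")
    return {
        "train": (years[0], years[-3]),
        "val": (years[-2], years[-2]),
        "test": (years[-1], years[-1]),
    }


def prepare_splits(
    th: TemporalHypergraph,
    split_years: dict | None = None,
    val_half_seed: int = 0,
    min_size: int | None = None,
    max_size: int | None = None,
) -> tuple[TemporalHypergraph, DatasetSplits]:
    """Optional size filtering, period split with validation halving, and
    leakage removal.  Returns the (possibly filtered) hypergraph and splits."""
    if min_size is not None or max_size is not None:
        th = filter_by_size(th, min_size or 5, max_size or 30)
    years = split_years or default_split_years(th)
    splits = remove_split_leakage(split_by_period(th, years, val_half_seed))
    return th, splits


def run_experiment(
    th: TemporalHypergraph,
    seed: int = 0,
    sampler: SamplerConfig | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    split_years: dict | None = None,
    eval_global: bool = True,
) -> RunResult:
    """Train on the training period and evaluate on the held-out final
    period, trails drawn from train plus the trail half of validation.
    Fully deterministic under ``seed``."""
    sampler = sampler or SamplerConfig(rng_seed=seed)
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig(seed=seed)
    loss_cfg = loss_cfg or LossConfig()

    th, splits = prepare_splits(th, split_years, val_half_seed=seed)
    instances = build_instances(splits, th, sampler)
    model = HyperedgePredictor.build(th, model_cfg, seed=seed,
                                     pe_edges=splits.train)

    def instance_factory(epoch_seed: int):
        cfg = SamplerConfig(
            r=sampler.r, predecessor_policy=sampler.predecessor_policy,
            per_step_negatives=sampler.per_step_negatives,
            allow_gap_skip=sampler.allow_gap_skip, rng_seed=epoch_seed)
        return build_instances(splits, th, cfg)

    val_fn = None
    if splits.val_opt:
        val_history = subgraph(th, splits.train)
        val_sampler = SamplerConfig(
            r=sampler.r, predecessor_policy=sampler.predecessor_policy,
            allow_gap_skip=sampler.allow_gap_skip, rng_seed=seed + 2)

        def val_fn(m):
            # balance the two discrimination tasks when selecting the epoch
            hard = evaluate_model(m, splits.val_opt, val_history, val_sampler,
                                  negative_kind="hard").auc
            glob = evaluate_model(m, splits.val_opt, val_history, val_sampler,
                                  negative_kind="global").auc
            return 0.5 * (hard + glob)

    trained = train(instances, model, train_cfg, loss_cfg,
                    instance_factory=instance_factory, val_fn=val_fn)

    history = subgraph(th, splits.train + splits.val_trail)
    eval_sampler = SamplerConfig(
        r=sampler.r, predecessor_policy=sampler.predecessor_policy,
        per_step_negatives=sampler.per_step_negatives,
        allow_gap_skip=sampler.allow_gap_skip, rng_seed=seed + 1)
    metrics_hard = evaluate_model(trained.model, splits.test, history,
                                  eval_sampler, negative_kind="hard")
    metrics_global = None
    if eval_global:
        metrics_global = evaluate_model(trained.model, splits.test, history,
                                        eval_sampler, negative_kind="global")
    return RunResult(model=trained, splits=splits,
                     metrics_hard=metrics_hard, metrics_global=metrics_global)
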