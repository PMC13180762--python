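"""Metrics, trail-aware evaluation protocol, consistency and ablation."""

import numpy as np
import pytest

from hypertrail.evaluation import (ablation_contribution, claim2_rate,
                                   compute_metrics, consistency,
                                   evaluate_model)
from hypertrail.hypergraph import split_by_period, subgraph
from hypertrail.sampling import SamplerConfig, build_instances
from hypertrail.synthetic import SyntheticConfig, simulate

from conftest import make_hypergraph


def brute_force_auc(scores, labels):
    """Pairwise-comparison AUC: concordant 1, tie 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeMetrics:
    def test_perfect_separation(self):
        rep = compute_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.auc == 1.0 and rep.average_precision == 1.0
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_inverted_labels_give_zero_auc(self):
        rep = compute_metrics([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])
        assert rep.auc == 0.0

    def test_interleaved_example(self):
        # pos-neg pairs: (0.9,0.8)+, (0.9,0.3)+, (0.4,0.8)-, (0.4,0.3)+
        rep = compute_metrics([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert rep.auc == pytest.approx(0.75)

    def test_matches_bruteforce_oracle_on_random_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores to exercise ties
            scores = np.round(rng.random(n), 1)
            rep = compute_metrics(scores, labels)
            assert rep.auc == pytest.approx(
                brute_force_auc(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_threshold_rule_counts_equal_as_positive(self):
        rep = compute_metrics([0.5, 0.5], [1, 0], threshold=0.5)
        assert rep.accuracy == 0.5  # both predicted positive

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([0.4, 0.6], [1, 1])

    def test_counts_reported(self):
        rep = compute_metrics([0.9, 0.1, 0.2], [1, 0, 0])
        assert rep.n_pos == 1 and rep.n_neg == 2


class _ConstantModel:
    """Stub predictor scoring every candidate 0.5."""

    def forward_sequence(self, edges, times=None):
        import numpy as np
        from hypertrail.autodiff import Tensor
        n = len(edges)
        return Tensor(np.zeros((n, 4))), Tensor(np.full((n, 1), 0.5)), []

    def forward_substituted(self, edges, times, tokens, k, negative,
                            neg_time=None):
        import numpy as np
        from hypertrail.autodiff import Tensor
        return Tensor(np.zeros((1, 4))), Tensor(np.full((1, 1), 0.5))


class TestEvaluateModel:
    def _setup(self):
        th, _ = simulate(SyntheticConfig(n_concepts=120, n_lineages=8, T=5,
                                         seed=4))
        bounds = {"train": (2000, 2002), "val": (2003, 2003),
                  "test": (2004, 2004)}
        splits = split_by_period(th, bounds, 0)
        history = subgraph(th, splits.train + splits.val_trail)
        return th, splits, history

    def test_constant_scorer_accuracy_half_on_balanced_pool(self):
        _, splits, history = self._setup()
        rep = evaluate_model(_ConstantModel(), splits.test, history,
                             SamplerConfig(rng_seed=1))
        # ties >= threshold count positive: all predicted positive
        assert rep.accuracy == 0.5
        assert rep.n_pos == rep.n_neg == len(splits.test)

    def test_no_targets_errors(self):
        _, _, history = self._setup()
        with pytest.raises(ValueError):
            evaluate_model(_ConstantModel(), [], history, SamplerConfig())

    def test_history_leak_asserts(self):
        th, splits, _ = self._setup()
        full_history = subgraph(th, list(th.hyperedges()))  # includes test year
        with pytest.raises(AssertionError):
            evaluate_model(_ConstantModel(), splits.test, full_history,
                           SamplerConfig())

    def test_deterministic_under_seed(self):
        from hypertrail.model import HyperedgePredictor, ModelConfig
        th, splits, history = self._setup()
        model = HyperedgePredictor.build(
            th, ModelConfig(d=8, d_time=4, n_heads=2), seed=0,
            pe_edges=splits.train)
        a = evaluate_model(model, splits.test, history,
                           SamplerConfig(rng_seed=9))
        b = evaluate_model(model, splits.test, history,
                           SamplerConfig(rng_seed=9))
        assert a.as_dict() == b.as_dict()


class TestClaim2Rate:
    def test_untrained_identical_tokens_tie_counts_as_failure(self):
        th, _ = simulate(SyntheticConfig(n_concepts=120, n_lineages=8, T=5,
                                         seed=4))
        bounds = {"train": (2000, 2002), "val": (2003, 2003),
                  "test": (2004, 2004)}
        splits = split_by_period(th, bounds, 0)
        # hard negatives identical to positives (r=0): distances tie exactly
        instances = build_instances(splits, th,
                                    SamplerConfig(r=0.0, rng_seed=1))
        from hypertrail.model import HyperedgePredictor, ModelConfig
        model = HyperedgePredictor.build(
            th, ModelConfig(d=8, d_time=4, n_heads=2), seed=0,
            pe_edges=splits.train)
        eligible = [i for i in instances if len(i.trail.sequence) > 1]
        assert eligible
        assert claim2_rate(model, instances) == 0.0

    def test_no_eligible_instances_errors(self):
        th, _ = simulate(SyntheticConfig(n_concepts=120, n_lineages=4, T=2,
                                         seed=4))
        bounds = {"train": (2000, 2000), "val": (2001, 2001),
                  "test": (2001, 2001)}
        # t=0 targets only -> empty trails everywhere
        splits = split_by_period(
            th, {"train": (2000, 2000), "val": (2001, 2001),
                 "test": (2002, 2002)}, 0)
        instances = build_instances(splits, th, SamplerConfig(rng_seed=1),
                                    targets=[e for e in splits.train
                                             if e.timestamp == 0])
        from hypertrail.model import HyperedgePredictor, ModelConfig
        model = HyperedgePredictor.build(
            th, ModelConfig(d=8, d_time=4, n_heads=2), seed=0,
            pe_edges=splits.train)
        with pytest.raises(ValueError):
            claim2_rate(model, instances)


class TestClaim1Curve:
    def test_plumbing_with_stub_trainer(self):
        from hypertrail.evaluation import claim1_curve
        # stub: AUC rises deterministically with r
        out = claim1_curve(lambda seed: seed, [0.1, 0.5, 0.9],
                           lambda ds, r, s: 0.5 + 0.4 * r, seeds=[0, 1])
        assert out["mean_auc_by_r"][0.9] > out["mean_auc_by_r"][0.1]
        assert out["rank_correlation"] == pytest.approx(1.0)

    def test_single_entry_grid(self):
        from hypertrail.evaluation import claim1_curve
        out = claim1_curve(lambda seed: seed, [0.3],
                           lambda ds, r, s: 0.6, seeds=[0])
        assert out["mean_auc_by_r"] == {0.3: 0.6}

    def test_unsorted_grid_rejected(self):
        from hypertrail.evaluation import claim1_curve
        with pytest.raises(ValueError):
            claim1_curve(lambda s: s, [0.9, 0.1], lambda ds, r, s: 0.5)


class TestConsistency:
    def test_published_style_cv(self):
        rep = consistency([0.959, 0.957, 0.887])
        assert rep.mean == pytest.approx(0.934, abs=5e-4)
        assert rep.std == pytest.approx(0.041, abs=5e-4)
        assert rep.cv_percent == pytest.approx(4.4, abs=0.05)

    def test_identical_values_zero_cv(self):
        assert consistency([0.8, 0.8, 0.8]).cv_percent == pytest.approx(0.0, abs=1e-12)

    def test_two_value_example(self):
        rep = consistency([1.0, 0.5])
        assert rep.mean == pytest.approx(0.75)
        assert rep.std == pytest.approx(0.35355, abs=1e-4)
        assert rep.cv_percent == pytest.approx(47.14, abs=0.01)

    def test_fewer_than_two_errors(self):
        with pytest.raises(ValueError):
            consistency([0.9])


class TestAblationContribution:
    def test_global_awareness_arithmetic(self):
        got = ablation_contribution(0.959, 0.744)
        assert got["absolute"] == pytest.approx(0.215, abs=1e-12)
        assert got["relative_percent"] == pytest.approx(22.4, abs=0.05)

    def test_contrastive_loss_arithmetic(self):
        got = ablation_contribution(0.959, 0.799)
        assert got["absolute"] == pytest.approx(0.160, abs=1e-12)
        assert got["relative_percent"] == pytest.approx(16.7, abs=0.05)

    def test_identity_gives_zero(self):
        got = ablation_contribution(0.7, 0.7)
        assert got["absolute"] == 0.0 and got["relative_percent"] == 0.0

    def test_zero_full_metric_errors(self):
        with pytest.raises(ValueError):
            ablation_contribution(0.0, 0.1)
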