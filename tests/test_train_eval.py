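"""Cross-validation plans, metrics, training behaviour, and ranking."""

import numpy as np
import pytest

from gcmm.errors import ConfigError
from gcmm.estimator import GCMM
from gcmm.train_eval import (
    ablation_estimator,
    evaluate_fold,
    make_cv_plan,
    predict_top_k,
    run_ablation,
    run_cv,
    score_metrics,
    sweep,
    train_fold,
)

from tests.oracles import auc_pairwise


def _fast_estimator(**kw):
    defaults = dict(
        n_epochs=60, init_dim=8, embedding_dim=16, n_out_channels=8,
        adjacency_top_k=8, x0_trainable=True, random_state=0,
    )
    defaults.update(kw)
    return GCMM(**defaults)


class TestCvPlan:
    def test_balanced_fold_sizes(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, seed=0)
        n_pos = int(small_net.assoc.values.sum())
        assert sum(len(f) for f in plan.positive_folds) == n_pos
        assert sum(len(f) for f in plan.negative_folds) == n_pos
        sizes = [len(f) for f in plan.positive_folds]
        assert max(sizes) - min(sizes) <= 1

    def test_folds_partition_positive_set(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, seed=3)
        seen = np.vstack(plan.positive_folds)
        expected = np.argwhere(small_net.assoc.values == 1)
        assert {tuple(r) for r in seen} == {tuple(r) for r in expected}
        assert len(seen) == len({tuple(r) for r in seen})

    def test_negatives_disjoint_from_positives(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, seed=1)
        for fold in plan.negative_folds:
            for i, j in fold:
                assert small_net.assoc.values[i, j] == 0

    def test_same_seed_identical_plans(self, small_net):
        p1 = make_cv_plan(small_net.assoc, k=5, seed=42)
        p2 = make_cv_plan(small_net.assoc, k=5, seed=42)
        for a, b in zip(p1.positive_folds + p1.negative_folds,
                        p2.positive_folds + p2.negative_folds):
            np.testing.assert_array_equal(a, b)

    def test_all_pairs_regime_covers_every_cell(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, regime="all_pairs", seed=0)
        n_cells = small_net.assoc.values.size
        covered = sum(len(f) for f in plan.positive_folds) + sum(
            len(f) for f in plan.negative_folds
        )
        assert covered == n_cells

    def test_too_few_positives_rejected(self, small_net):
        from gcmm.hetnet import AssociationMatrix

        tiny = AssociationMatrix(
            small_net.drug_ids, small_net.disease_ids,
            np.zeros(small_net.assoc.shape, dtype=np.int8),
        )
        tiny.values[0, 0] = 1
        with pytest.raises(ValueError, match="positives"):
            make_cv_plan(tiny, k=5)


class TestScoreMetrics:
    def test_hand_computed_confusion_table(self):
        # TP=8, FP=2, TN=7, FN=3 at threshold 0.5 on pre-scaled scores
        scores = np.array([0.9] * 8 + [0.1] * 3 + [0.9] * 2 + [0.1] * 7)
        labels = np.array([1] * 11 + [0] * 9)
        metrics, counts = score_metrics(scores, labels, scale=False)
        assert (counts.TP, counts.FP, counts.TN, counts.FN) == (8, 2, 7, 3)
        assert metrics["Precision"] == pytest.approx(0.8)
        assert metrics["Recall"] == pytest.approx(8 / 11)
        assert metrics["ACC"] == pytest.approx(0.75)
        assert metrics["Specificity"] == pytest.approx(7 / 9)
        p, r = 0.8, 8 / 11
        assert metrics["F1"] == pytest.approx(2 * p * r / (p + r))

    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        metrics, _ = score_metrics(scores, labels)
        assert metrics["AUC"] == 1.0
        assert metrics["AUPR"] == 1.0

    def test_auc_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 200))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            metrics, _ = score_metrics(scores, labels)
            assert metrics["AUC"] == pytest.approx(
                auc_pairwise(scores, labels), abs=1e-10
            )

    def test_random_scores_auc_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        metrics, _ = score_metrics(scores, labels)
        assert metrics["AUC"] == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            score_metrics(np.array([0.1, 0.9]), np.array([1, 1]))


class TestTraining:
    def test_zero_learning_rate_flat_trajectory(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, seed=0)
        est = _fast_estimator(learning_rate=0.0, n_epochs=5)
        model = train_fold(small_net, plan, 0, est)
        assert np.ptp(model.loss_curve_) == 0.0

    def test_loss_descends_on_planted_network(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, seed=0)
        model = train_fold(small_net, plan, 0, _fast_estimator())
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_fixed_seed_bit_identical_trajectory(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=5, seed=0)
        m1 = train_fold(small_net, plan, 0, _fast_estimator(n_epochs=20))
        m2 = train_fold(small_net, plan, 0, _fast_estimator(n_epochs=20))
        np.testing.assert_array_equal(m1.loss_curve_, m2.loss_curve_)
        np.testing.assert_array_equal(m1.U_, m2.U_)


class TestRunCv:
    def test_report_shape_and_mean_row(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        report = run_cv(small_net, plan, _fast_estimator(n_epochs=30))
        assert len(report.per_fold) == 3
        frame = report.as_frame()
        assert list(frame.index) == ["Fold 1", "Fold 2", "Fold 3", "Mean"]
        for name in ("AUC", "AUPR", "F1"):
            assert report.mean[name] == pytest.approx(
                np.mean([f[name] for f in report.per_fold]), abs=1e-12
            )

    def test_confusion_counts_cover_validation_fold(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        est = _fast_estimator(n_epochs=30)
        model = train_fold(small_net, plan, 1, est)
        _, counts = evaluate_fold(model, plan, 1)
        pairs, _ = plan.validation_pairs(1)
        assert counts.total == len(pairs)


class TestAblation:
    def test_full_variant_equals_run_cv(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        est = _fast_estimator(n_epochs=25)
        r1 = run_cv(small_net, plan, est)
        r2 = run_ablation(small_net, "full", plan, est)
        assert r1.per_fold == r2.per_fold

    def test_no_att_differs_only_through_attention_path(self, small_net):
        est = ablation_estimator("no_att", _fast_estimator())
        assert est.attention is False and est.extractor is True

    def test_view_subset_shrinks_channels(self, small_net):
        est = ablation_estimator("C+M", _fast_estimator())
        assert est.drug_views == ("C",) and est.disease_views == ("M",)
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        report = run_cv(small_net, plan, est.set_params(n_epochs=25))
        assert len(report.per_fold) == 3

    def test_empty_family_subset_rejected(self):
        with pytest.raises(ConfigError):
            ablation_estimator("C+T")


class TestSweep:
    def test_one_report_per_value(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        table = sweep(small_net, "layers", [1, 2], plan, _fast_estimator(n_epochs=20))
        assert list(table.index) == [1, 2]

    def test_deterministic_under_fixed_seed(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        t1 = sweep(small_net, "lr", [0.001, 0.01], plan, _fast_estimator(n_epochs=15))
        t2 = sweep(small_net, "lr", [0.001, 0.01], plan, _fast_estimator(n_epochs=15))
        assert t1.equals(t2)

    def test_needs_two_values(self, small_net):
        plan = make_cv_plan(small_net.assoc, k=3, seed=0)
        with pytest.raises(ConfigError):
            sweep(small_net, "layers", [2], plan)


class TestPredictTopK:
    def test_known_associations_excluded(self, small_net):
        est = _fast_estimator(n_epochs=40).fit(small_net)
        disease = small_net.disease_ids[0]
        j = 0
        known = {
            small_net.drug_ids[i]
            for i in np.nonzero(small_net.assoc.values[:, j])[0]
        }
        ranked = predict_top_k(est, small_net, disease, k=10)
        assert known.isdisjoint({d for d, _ in ranked})

    def test_k_larger_than_candidates_returns_all(self, small_net):
        est = _fast_estimator(n_epochs=10).fit(small_net)
        disease = small_net.disease_ids[0]
        n_unknown = int((small_net.assoc.values[:, 0] == 0).sum())
        ranked = predict_top_k(est, small_net, disease, k=10_000)
        assert len(ranked) == n_unknown

    def test_unknown_disease_rejected(self, small_net):
        est = _fast_estimator(n_epochs=5).fit(small_net)
        with pytest.raises(KeyError):
            predict_top_k(est, small_net, "not-a-disease")

    def test_scores_sorted_descending(self, small_net):
        est = _fast_estimator(n_epochs=40).fit(small_net)
        ranked = predict_top_k(est, small_net, small_net.disease_ids[3], k=8)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_held_out_planted_drug_recovered_in_top5(self):
        """Monte-Carlo: a masked planted association reranks into the top 5."""
        from gcmm.hetnet import AssociationMatrix
        from gcmm.similarity import build_network
        from gcmm.synthetic import SyntheticSpec, generate

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            b = generate(
                SyntheticSpec(n_drugs=30, n_diseases=20, n_clusters=3,
                              n_targets=9, seed=seed)
            )
            planted = np.argwhere(
                (b.assoc.values == 1) & (b.clean_assoc.values == 1)
            )
            i, j = planted[seed % len(planted)]
            held_out = b.assoc.values.copy()
            held_out[i, j] = 0
            assoc = AssociationMatrix(b.assoc.drug_ids, b.assoc.disease_ids, held_out)
            net = build_network(
                b.drugs, b.diseases, b.dag, b.target_sequences, assoc
            )
            # train in the balanced regime: positives + equal sampled
            # negatives, never including the held-out cell as a negative
            plan = make_cv_plan(assoc, k=2, regime="balanced", seed=seed)
            pairs = np.vstack(plan.positive_folds + plan.negative_folds)
            pairs = pairs[~((pairs[:, 0] == i) & (pairs[:, 1] == j))]
            from gcmm.benchmark import benchmark_estimator

            est = benchmark_estimator(seed=seed).fit(net, mask=pairs)
            top = predict_top_k(est, net, net.disease_ids[j], k=5)
            hits += net.drug_ids[i] in {d for d, _ in top}
        assert hits >= 0.8 * n_seeds
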