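import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfusion.spatial_gcn import SGCM, SGCMConfig, default_electrode_graph
from eegfusion.temporal_transformer import TTM, TTMConfig
from eegfusion.training_eval import (CPDDataset, TrainConfig,
                                     compute_metrics, extract_features,
                                     make_subject_folds, roc_auc,
                                     run_experiment, subset_classes,
                                     train_stage1, train_stage2,
                                     _state_hash)

TINY_TTM = TTMConfig(patch_size=8, embed_dim=16, depth=1, n_heads=2, n_classes=3)


class TestFolds:
    def test_counting(self):
        sids = [f"s{i}" for i in range(30)]
        labels = [i % 3 for i in range(30)]
        plan = make_subject_folds(sids, labels, k=10, seed=0)
        sizes = [len(plan.test_subjects(f)) for f in range(10)]
        assert sizes == [3] * 10

    def test_partition_property(self):
        sids = [f"s{i}" for i in range(23)]
        labels = [i % 3 for i in range(23)]
        plan = make_subject_folds(sids, labels, k=5, seed=1)
        all_subjects = set()
        for f in range(5):
            fold_subjects = plan.test_subjects(f)
            assert not (fold_subjects & all_subjects)   # disjoint
            all_subjects |= fold_subjects
        assert all_subjects == set(sids)                # exhaustive

    def test_subject_segments_share_fold(self):
        # subject s0 contributes 7 samples; the plan is per-subject so all 7
        # land wherever s0 lands
        sids = ["s0"] * 7 + [f"s{i}" for i in range(1, 12)]
        labels = [0] * 7 + [i % 2 for i in range(1, 12)]
        plan = make_subject_folds(sids, labels, k=3, seed=2)
        folds = {plan.assignments[s] for s in sids}
        assert plan.assignments["s0"] in folds
        assert len({plan.assignments["s0"]}) == 1

    def test_fewer_subjects_than_folds(self):
        with pytest.raises(ValueError):
            make_subject_folds(["a", "b"], [0, 1], k=3)

    def test_conflicting_labels_rejected(self):
        with pytest.raises(ValueError):
            make_subject_folds(["a", "a"], [0, 1], k=1)

    def test_stratified_balance(self):
        # 20 subjects per class, k=10 -> every fold gets 2 of each class
        sids = [f"c{c}s{i}" for c in range(3) for i in range(20)]
        labels = [c for c in range(3) for _ in range(20)]
        plan = make_subject_folds(sids, labels, k=10, seed=3)
        for f in range(10):
            per_class = [sum(1 for s in plan.test_subjects(f) if s.startswith(f"c{c}"))
                         for c in range(3)]
            assert per_class == [2, 2, 2]


class TestComputeMetrics:
    def test_hand_case_tp3_tn4_fp1_fn2(self):
        y_true = [1] * 3 + [0] * 4 + [0] + [1] * 2
        y_pred = [1] * 3 + [0] * 4 + [1] + [0] * 2
        rep = compute_metrics(y_true, y_pred, 2)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.recall == pytest.approx(0.6)
        assert rep.precision == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))
        assert rep.f1 == pytest.approx(0.6667, abs=1e-4)

    def test_perfect_predictions(self):
        y = [0, 1, 2, 1, 0, 2]
        rep = compute_metrics(y, y, 3)
        assert rep.accuracy == rep.recall == rep.precision == rep.f1 == 1.0
        assert np.array_equal(rep.confusion, np.diag([2, 2, 2]))

    def test_degenerate_all_one_class(self):
        rep = compute_metrics([0, 1, 0, 1], [1, 1, 1, 1], 2)
        assert rep.per_class["0"]["precision"] == 0.0
        assert rep.per_class["0"]["recall"] == 0.0
        assert rep.recall == 1.0       # positive class fully recalled

    def test_label_validation(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 3], [0, 1], 2)
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0], 2)

    def test_multiclass_macro_average(self):
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 2, 0]
        rep = compute_metrics(y_true, y_pred, 3)
        per = rep.per_class
        assert rep.precision == pytest.approx(
            np.mean([per[c]["precision"] for c in per]))
        assert rep.f1 == pytest.approx(np.mean([per[c]["f1"] for c in per]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=1, max_size=40))
    def test_confusion_consistency_property(self, pairs):
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        rep = compute_metrics(y_true, y_pred, 3)
        assert rep.confusion.sum() == len(pairs)
        for c in range(3):
            assert rep.confusion[c].sum() == y_true.count(c)
        assert rep.accuracy == pytest.approx(np.mean(np.array(y_true) == np.array(y_pred)))
        assert 0 <= rep.f1 <= 1 and 0 <= rep.recall <= 1 and 0 <= rep.precision <= 1


class TestRocAuc:
    def test_one_hot_scores(self):
        y = np.array([0, 1, 2, 1])
        scores = np.eye(3)[y]
        assert np.allclose(roc_auc(y, scores), 1.0)

    def test_constant_scores(self):
        y = np.array([0, 1, 0, 1])
        scores = np.full((4, 2), 0.5)
        assert np.allclose(roc_auc(y, scores), 0.5)

    def test_mann_whitney_hand_case(self):
        scores_pos = np.array([0.9, 0.8, 0.4, 0.3])
        y = np.array([1, 0, 1, 0])
        # independent oracle: fraction of (positive, negative) pairs ranked
        # correctly, ties counting one half
        pos = scores_pos[y == 1]
        neg = scores_pos[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert oracle == 0.75
        scores = np.column_stack([1 - scores_pos, scores_pos])
        assert roc_auc(y, scores)[1] == pytest.approx(oracle)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc(np.zeros(4, dtype=int), np.random.default_rng(0).random((4, 2)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0, 1]), np.array([[np.inf, 0.0], [0.0, 1.0]]))


@pytest.fixture(scope="module")
def trained_stage1(small_dataset):
    """Short stage-1 training on the separable 6-subject cohort."""
    model = TTM(TINY_TTM, small_dataset.map_shape, rng=0)
    cfg = TrainConfig.test_profile(stage1_epochs=10)
    result = train_stage1(model, small_dataset, cfg,
                          rng=np.random.default_rng(0), eval_ds=small_dataset)
    return result


class TestStage1:
    def test_loss_decreases(self, trained_stage1):
        hist = trained_stage1.history
        assert hist[-1] < hist[0]

    def test_above_chance_per_channel(self, trained_stage1):
        accs = trained_stage1.channel_accuracy
        assert set(accs) == set("Fp1 Fp2 F3 F4 C3 C4 P3 P4 O1 O2 F7 F8 "
                                "T3 T4 T5 T6".split())
        assert all(a > 0.34 for a in accs.values())

    def test_zero_lr_leaves_parameters(self, small_dataset):
        model = TTM(TINY_TTM, small_dataset.map_shape, rng=1)
        before = _state_hash(model)
        cfg = TrainConfig.test_profile(stage1_epochs=2, stage1_lr=0.0)
        train_stage1(model, small_dataset, cfg, rng=0)
        assert _state_hash(model) == before

    def test_single_class_degenerate(self, small_dataset):
        ds = subset_classes(small_dataset, ["control"])
        model = TTM(TTMConfig(patch_size=8, embed_dim=16, depth=1, n_heads=2,
                              n_classes=1), ds.map_shape, rng=2)
        cfg = TrainConfig.test_profile(stage1_epochs=3)
        res = train_stage1(model, ds, cfg, rng=0, eval_ds=ds)
        assert all(a == 1.0 for a in res.channel_accuracy.values())
        assert res.history[-1] <= res.history[0]

    def test_empty_dataset_rejected(self, small_dataset):
        empty = CPDDataset(X=small_dataset.X[:0], y=small_dataset.y[:0],
                           subject_ids=small_dataset.subject_ids[:0],
                           channels=small_dataset.channels,
                           class_names=small_dataset.class_names,
                           freq_axis=small_dataset.freq_axis)
        model = TTM(TINY_TTM, small_dataset.map_shape, rng=0)
        with pytest.raises(ValueError):
            train_stage1(model, empty, TrainConfig.test_profile(), rng=0)


class TestStage2:
    @pytest.fixture
    def graph(self):
        return default_electrode_graph()

    def test_freeze_contract_and_training(self, trained_stage1, small_dataset, graph):
        ttm = trained_stage1.model
        before = _state_hash(ttm)
        sgcm = SGCM(SGCMConfig(), in_dim=TINY_TTM.embed_dim, rng=0)
        cfg = TrainConfig.test_profile()
        res = train_stage2(sgcm, ttm, small_dataset, graph, cfg, rng=0)
        assert _state_hash(ttm) == before          # bit-identical stage-1 weights
        assert res.history[-1] < res.history[0]

    def test_zero_lr_stage2(self, trained_stage1, small_dataset, graph):
        sgcm = SGCM(SGCMConfig(), in_dim=TINY_TTM.embed_dim, rng=1)
        before = _state_hash(sgcm)
        cfg = TrainConfig.test_profile(stage2_epochs=2, stage2_lr=0.0)
        train_stage2(sgcm, trained_stage1.model, small_dataset, graph, cfg, rng=0)
        assert _state_hash(sgcm) == before

    def test_feature_shapes(self, trained_stage1, small_dataset):
        feats = extract_features(trained_stage1.model, small_dataset)
        assert feats.shape == (small_dataset.n_segments, 16, TINY_TTM.embed_dim)
        assert np.isfinite(feats).all()

    def test_graph_channel_order_enforced(self, trained_stage1, small_dataset):
        from eegfusion.spatial_gcn import build_graph
        wrong = build_graph(("C3", "C4"), [("C3", "C4")])
        sgcm = SGCM(SGCMConfig(), in_dim=TINY_TTM.embed_dim, rng=0)
        with pytest.raises(ValueError):
            train_stage2(sgcm, trained_stage1.model, small_dataset, wrong,
                         TrainConfig.test_profile(), rng=0)


class TestSubsetClasses:
    def test_pairwise_subset(self, small_dataset):
        ds = subset_classes(small_dataset, ["control", "viral"])
        assert ds.class_names == ("control", "viral")
        assert set(ds.y) == {0, 1}
        assert ds.n_segments == 4
        with pytest.raises(ValueError):
            subset_classes(small_dataset, ["control", "control"])


class TestRunExperiment:
    def test_small_cv_run_and_invariants(self, small_dataset):
        graph = default_electrode_graph()
        cfg = TrainConfig.test_profile(stage1_epochs=3, stage2_epochs=4, seed=5)
        result = run_experiment(small_dataset, graph, cfg, ttm_cfg=TINY_TTM,
                                k=3, seed=5)
        assert len(result.folds) == 3
        # confusion aggregates to the full segment count
        assert result.confusion_total.sum() == small_dataset.n_segments
        # per-fold confusion row sums match per-class test counts
        for fo in result.folds:
            test_mask = np.isin(small_dataset.subject_ids, fo.test_subjects)
            counts = np.bincount(small_dataset.y[test_mask], minlength=3)
            assert np.array_equal(fo.report.confusion.sum(axis=1), counts)
        # subject exclusivity across folds
        seen = set()
        for fo in result.folds:
            assert not (set(fo.test_subjects) & seen)
            seen |= set(fo.test_subjects)
        for key in ("accuracy", "recall", "precision", "f1"):
            assert 0.0 <= result.mean_metrics[key] <= 1.0

    def test_pairwise_binary_report(self, small_dataset):
        graph = default_electrode_graph()
        cfg = TrainConfig.test_profile(stage1_epochs=2, stage2_epochs=2, seed=3)
        result = run_experiment(small_dataset, graph, cfg, ttm_cfg=TINY_TTM,
                                classes=["control", "viral"], k=2, seed=3)
        assert result.class_names == ("control", "viral")
        assert result.confusion_total.shape == (2, 2)

    def test_deterministic_given_seed(self, small_dataset):
        graph = default_electrode_graph()
        cfg = TrainConfig.test_profile(stage1_epochs=2, stage2_epochs=2, seed=9)
        a = run_experiment(small_dataset, graph, cfg, ttm_cfg=TINY_TTM, k=2, seed=9)
        b = run_experiment(small_dataset, graph, cfg, ttm_cfg=TINY_TTM, k=2, seed=9)
        assert a.mean_metrics == b.mean_metrics
        assert np.array_equal(a.confusion_total, b.confusion_total)
        assert a.fold_plan.assignments == b.fold_plan.assignments
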