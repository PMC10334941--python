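"""Training loop behaviour: folds, schedules, determinism, loss isolation."""

import numpy as np
import pytest

from tripoint.losses import LossWeights
from tripoint.nn import Param, SGD
from tripoint.training import (
    ArrayDataset,
    ReduceLROnPlateau,
    TrainConfig,
    cross_validate,
    five_fold_cv,
    train_semisupervised,
    train_supervised,
)
from tripoint.workbench import datasets_from_synthetic


@pytest.fixture(scope="module")
def small_data(tiny_synth):
    labeled, unlabeled, val, holdout = datasets_from_synthetic(tiny_synth)
    return labeled, unlabeled, val, holdout


class TestFiveFoldCV:
    def test_900_ids_give_folds_of_180(self):
        rng = np.random.default_rng(0)
        ids = [f"im{i}" for i in range(900)]
        labels = np.repeat([0, 1], 450)
        folds = five_fold_cv(ids, labels, seed=4)
        assert len(folds) == 5
        assert all(len(f.val_ids) == 180 for f in folds)

    def test_val_folds_partition_the_ids(self):
        ids = [f"im{i}" for i in range(103)]
        labels = np.random.default_rng(1).integers(0, 2, size=103)
        folds = five_fold_cv(ids, labels, seed=0)
        all_val = [i for f in folds for i in f.val_ids]
        assert sorted(all_val) == sorted(ids)
        for f in folds:
            assert set(f.train_ids).isdisjoint(f.val_ids)
            assert sorted(f.train_ids + f.val_ids) == sorted(ids)

    def test_stratification_within_one(self):
        ids = list(range(900))
        labels = np.repeat([0, 1], 450)
        for f in five_fold_cv(ids, labels, seed=9):
            n_pos = sum(labels[i] for i in f.val_ids)
            assert abs(n_pos - 90) <= 1

    def test_fewer_ids_than_folds_rejected(self):
        with pytest.raises(ValueError):
            five_fold_cv([1, 2, 3], [0, 1, 0], seed=0)


class TestPlateauSchedule:
    def test_rate_halves_after_patience_plus_one_stagnant_epochs(self):
        opt = SGD([Param(np.zeros(1))], lr=0.01)
        sched = ReduceLROnPlateau(opt, factor=0.5, threshold=0.01, patience=7)
        sched.step(1.0)  # becomes best
        for _ in range(7):
            sched.step(1.0)
            assert opt.lr == 0.01
        sched.step(1.0)  # 8th stagnant epoch = patience + 1
        assert opt.lr == 0.005

    def test_improvement_resets_the_counter(self):
        opt = SGD([Param(np.zeros(1))], lr=0.1)
        sched = ReduceLROnPlateau(opt, factor=0.5, threshold=0.01, patience=2)
        for v in [1.0, 1.0, 1.0, 0.5, 0.5, 0.5]:
            sched.step(v)
        assert opt.lr == 0.1
        sched.step(0.5)
        assert opt.lr == 0.05

    def test_relative_threshold(self):
        opt = SGD([Param(np.zeros(1))], lr=0.1)
        sched = ReduceLROnPlateau(opt, factor=0.5, threshold=0.01, patience=0)
        sched.step(1.0)
        sched.step(0.995)  # less than 1% better: stagnant
        assert opt.lr == 0.05


class TestTrainingLoops:
    def test_same_seed_same_history(self, small_data):
        labeled, _, val, _ = small_data
        cfg = TrainConfig(seed=5, max_epochs=3, loss_weights=LossWeights(1, 0, 0, 0))
        _, h1 = train_supervised(labeled, cfg, val=val)
        _, h2 = train_supervised(labeled, cfg, val=val)
        assert h1 == h2

    def test_semisup_reduces_to_supervised_without_cl(self, small_data):
        labeled, unlabeled, val, _ = small_data
        cfg = TrainConfig(seed=3, max_epochs=3, labeled_fraction_per_batch=1.0,
                          loss_weights=LossWeights(1, 1, 1, 0))
        _, h_sup = train_supervised(labeled, cfg, val=val)
        _, h_semi = train_semisupervised(labeled, unlabeled, cfg, val=val)
        assert h_sup == h_semi

    def test_disabled_feature_losses_never_read_feature_labels(self, tiny_synth):
        labeled, unlabeled, val, _ = datasets_from_synthetic(tiny_synth)
        labeled.feature_reads = 0
        cfg = TrainConfig(seed=0, max_epochs=2, loss_weights=LossWeights(1, 0, 0, 1))
        train_semisupervised(labeled, unlabeled, cfg, val=val)
        assert labeled.feature_reads == 0

    def test_feature_loss_without_labels_rejected_at_startup(self, small_data):
        labeled, _, val, _ = small_data
        bare = ArrayDataset(labeled.images, labeled.disease)  # no features
        cfg = TrainConfig(seed=0, max_epochs=1, loss_weights=LossWeights(1, 1, 0, 0))
        with pytest.raises(ValueError, match="feature"):
            train_supervised(bare, cfg)

    def test_cl_without_unlabeled_warns_and_degrades(self, small_data):
        labeled, _, val, _ = small_data
        cfg = TrainConfig(seed=0, max_epochs=1, loss_weights=LossWeights(1, 0, 0, 1))
        with pytest.warns(UserWarning, match="no unlabeled"):
            train_semisupervised(labeled, None, cfg, val=val)

    def test_overfits_its_own_training_split(self, small_data):
        """Disease-only training drives training accuracy high on a tiny set."""
        labeled, _, _, _ = small_data
        cfg = TrainConfig(seed=2, max_epochs=30, batch_size=16, augment=False,
                          loss_weights=LossWeights(1, 0, 0, 0))
        _, hist = train_supervised(labeled, cfg)
        assert hist[-1]["train_accuracy"] > 0.9

    def test_history_records_all_four_components(self, small_data):
        labeled, unlabeled, val, _ = small_data
        cfg = TrainConfig(seed=1, max_epochs=2)
        _, hist = train_semisupervised(labeled, unlabeled, cfg, val=val)
        assert {"dsl", "fsl", "rl", "cl", "lr", "val_loss"} <= set(hist[0])

    def test_teacher_params_carry_no_gradients(self, small_data):
        labeled, _, val, _ = small_data
        cfg = TrainConfig(seed=0, max_epochs=1, loss_weights=LossWeights(1, 0, 0, 0))
        state, _ = train_supervised(labeled, cfg, val=val)
        assert all(np.all(p.grad == 0) for p in state.teacher.params())

    def test_cross_validation_reports_per_fold_mean_and_sd(self, small_data):
        labeled, _, _, _ = small_data
        cfg = TrainConfig(seed=1, max_epochs=2, loss_weights=LossWeights(1, 0, 0, 0))
        accs, (mean, sd) = cross_validate(labeled, cfg, n_folds=5)
        assert len(accs) == 5
        assert mean == pytest.approx(np.mean(accs))
        assert sd == pytest.approx(np.std(accs, ddof=1))
        assert all(0.0 <= a <= 1.0 for a in accs)

    def test_teacher_scored_ranking_pairs_include_unlabeled(self, small_data):
        """ranking_source='teacher' trains with pseudo-scores on unlabeled data."""
        labeled, unlabeled, val, _ = small_data
        cfg = TrainConfig(seed=4, max_epochs=2, ranking_source="teacher",
                          loss_weights=LossWeights(1, 1, 1, 1))
        _, hist = train_semisupervised(labeled, unlabeled, cfg, val=val)
        assert all(np.isfinite(h["rl"]) for h in hist)

    def test_teacher_trajectory_smoother_than_student(self, small_data):
        """The EMA teacher's parameter path has smaller step-to-step motion."""
        labeled, _, val, _ = small_data
        moves = {"student": [], "teacher": []}
        prev = {}

        def hook(state, record):
            for name, net in (("student", state.student), ("teacher", state.teacher)):
                w = net.params()[0].value.copy()
                if name in prev:
                    moves[name].append(np.linalg.norm(w - prev[name]))
                prev[name] = w

        cfg = TrainConfig(seed=6, max_epochs=10, loss_weights=LossWeights(1, 0, 0, 0))
        train_supervised(labeled, cfg, val=val, epoch_hook=hook)
        # skip the EMA warm-up epochs where the teacher intentionally tracks
        assert np.mean(moves["teacher"][3:]) < np.mean(moves["student"][3:])
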