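"""Cross-validation fold plan, early stopping and the training loop."""

import math

import numpy as np
import pytest

from splicecode import (DSCConfig, build_dsc, encode_dataset, generate_dataset,
                        make_fold_plan, permute_labels, run_cv, train_fold)
from splicecode.simulate import SyntheticConfig
from splicecode.training import N_FOLDS, epoch_sweep

FAST_CONFIG = DSCConfig(branch_filters=(4, 8), branch_kernels=(7, 4),
                        dense_units=32)


class TestFoldPlan:
    @pytest.mark.parametrize("n,sizes", [
        (100, [10] * 10),
        (105, [11] * 5 + [10] * 5),
        (10, [1] * 10),
    ])
    def test_fold_sizes_balanced(self, n, sizes):
        assert sorted(make_fold_plan(n, seed=0).fold_sizes(), reverse=True) == \
            sorted(sizes, reverse=True)

    def test_folds_partition_the_samples(self):
        plan = make_fold_plan(97, seed=3)
        all_idx = np.concatenate([plan.fold_indices(f) for f in range(N_FOLDS)])
        assert sorted(all_idx) == list(range(97))

    def test_rotation_roles_disjoint_and_exhaustive(self):
        plan = make_fold_plan(100, seed=1)
        test_folds = []
        for r, rot in enumerate(plan.rotations):
            roles = {*rot.train_folds, rot.earlystop_fold, rot.test_fold}
            assert len(rot.train_folds) == 8
            assert rot.earlystop_fold not in rot.train_folds
            assert rot.test_fold not in rot.train_folds
            assert rot.earlystop_fold != rot.test_fold
            assert roles == set(range(N_FOLDS))
            test_folds.append(rot.test_fold)
        assert sorted(test_folds) == list(range(N_FOLDS))

    def test_each_sample_tested_exactly_once(self):
        plan = make_fold_plan(53, seed=9)
        tested = np.concatenate([plan.rotation_indices(r)[2] for r in range(N_FOLDS)])
        assert sorted(tested) == list(range(53))

    def test_deterministic_given_seed(self):
        a, b = make_fold_plan(80, seed=7), make_fold_plan(80, seed=7)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert not np.array_equal(a.fold_of, make_fold_plan(80, seed=8).fold_of)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_fold_plan(9, seed=0)


def small_planted_data(n_per_class=60, seed=5, signal=1.0):
    recs = generate_dataset(SyntheticConfig(n_per_class=n_per_class,
                                            signal_strength=signal, seed=seed))
    return encode_dataset(recs)


def split(data, n_train):
    return tuple(a[:n_train] for a in data), tuple(a[n_train:] for a in data)


class TestTrainFold:
    def test_loss_decreases_on_planted_signal(self):
        train, es = split(small_planted_data(), 100)
        net = build_dsc(FAST_CONFIG, seed=1)
        _, hist = train_fold(net, train, es, max_epochs=10, seed=1)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == hist.stopped_epoch <= 10

    def test_permuted_labels_plateau_near_ln2(self):
        data = small_planted_data(n_per_class=80)
        recs = generate_dataset(SyntheticConfig(n_per_class=80,
                                                signal_strength=1.0, seed=5))
        null = encode_dataset(permute_labels(recs, seed=6))
        train, es = split(null, 130)
        net = build_dsc(FAST_CONFIG, seed=2)
        _, hist = train_fold(net, train, es, max_epochs=8, seed=2)
        assert hist.earlystop_loss[-1] == pytest.approx(math.log(2), abs=0.12)

    def test_identical_seed_gives_identical_history(self):
        train, es = split(small_planted_data(n_per_class=30), 40)
        hists = []
        for _ in range(2):
            net = build_dsc(FAST_CONFIG, seed=3)
            _, h = train_fold(net, train, es, max_epochs=4, seed=4)
            hists.append(h)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].earlystop_loss == hists[1].earlystop_loss

    def test_restored_weights_come_from_best_earlystop_epoch(self):
        train, es = split(small_planted_data(n_per_class=40), 60)
        net = build_dsc(FAST_CONFIG, seed=5)
        net, hist = train_fold(net, train, es, max_epochs=12, seed=5, patience=3)
        best = int(np.argmin(hist.earlystop_loss)) + 1
        assert hist.best_epoch <= best  # min_delta may skip marginal gains
        # the restored model reproduces the best epoch's early-stop loss
        from splicecode.architecture import binary_cross_entropy
        from splicecode.training import _predict_proba_batched
        p = _predict_proba_batched(net, *es[:3])
        assert binary_cross_entropy(es[3], p) == pytest.approx(
            min(hist.earlystop_loss), abs=1e-6)

    def test_early_stopping_halts_before_max_epochs_on_noise(self):
        rng = np.random.default_rng(0)
        n = 60
        data = (rng.random((n, 140, 4), dtype=np.float32),
                rng.random((n, 140, 4), dtype=np.float32),
                rng.random((n, 3)).astype(np.float32),
                (np.arange(n) % 2).astype(np.float32))
        train, es = split(data, 40)
        net = build_dsc(FAST_CONFIG, seed=6)
        _, hist = train_fold(net, train, es, max_epochs=200, seed=6,
                             patience=3, min_delta=1e-3)
        assert hist.stopped_epoch < 200

    def test_empty_training_set_rejected(self):
        data = small_planted_data(n_per_class=10)
        empty = tuple(a[:0] for a in data)
        net = build_dsc(FAST_CONFIG, seed=0)
        with pytest.raises(ValueError, match="empty training set"):
            train_fold(net, empty, data, max_epochs=1)


class TestRunCv:
    def test_report_has_ten_folds_and_is_deterministic(self, tiny_records):
        rep1 = run_cv(tiny_records, FAST_CONFIG, max_epochs=2, seed=0)
        rep2 = run_cv(tiny_records, FAST_CONFIG, max_epochs=2, seed=0)
        assert len(rep1.fold_aucs) == N_FOLDS
        assert rep1.fold_aucs == rep2.fold_aucs
        assert rep1.mean_auc == pytest.approx(np.mean(rep1.fold_aucs))
        assert rep1.model_name == "dsc"

    def test_strong_signal_recovers_high_auc_quick(self):
        recs = generate_dataset(SyntheticConfig(n_per_class=100,
                                                signal_strength=1.0, seed=5))
        rep = run_cv(recs, FAST_CONFIG, max_epochs=40, seed=1, batch_size=32)
        assert rep.mean_auc >= 0.8  # small n; full-scale check elsewhere


class TestEpochSweep:
    def test_table_shape_and_range(self, tiny_records):
        result = epoch_sweep(tiny_records, FAST_CONFIG, epochs_list=(1, 2), seed=0)
        assert list(result.table.index) == [1, 2]
        assert list(result.table.columns) == ["existing_mean_auc", "updated_mean_auc"]
        assert ((result.table >= 0) & (result.table <= 1)).all().all()
        assert set(result.reports) == {(1, "existing"), (1, "updated"),
                                       (2, "existing"), (2, "updated")}

    def test_empty_epoch_list_rejected(self, tiny_records):
        with pytest.raises(ValueError, match="non-empty"):
            epoch_sweep(tiny_records, FAST_CONFIG, epochs_list=())
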