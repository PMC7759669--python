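import numpy as np
import pytest

from stsanet.evaluation import accuracy
from stsanet.model import ModelConfig, STSANet
from stsanet.synthetic import RhythmEffect, SyntheticSpec, generate_dataset
from stsanet.training import (
    TrainConfig,
    crossval_10fold,
    fit_two_phase,
    kfold_indices,
    split_train_valid,
    transfer_pretrain_finetune,
)


def small_spec():
    """A fast 6-channel, 1-second spec with one modulated group per class."""
    groups = ((0, 1), (2, 3), (4,), (5,))
    classes = [
        [RhythmEffect(g, "mu", 3.0), RhythmEffect(g, "beta", 0.3)]
        for g in groups
    ]
    return SyntheticSpec(n_channels=6, epoch_length_s=1.0, classes=classes)


def small_model():
    m = STSANet(
        ModelConfig(
            n_channels=6, n_samples=250, att_maps=4, head_maps=8,
            temporal_kernel=25, pool_kernel=75, pool_stride=15, n_classes=4,
        )
    )
    return m


@pytest.fixture(scope="module")
def small_data():
    return generate_dataset(small_spec(), 12, seed=7)  # 48 trials


class TestInitParameters:
    def test_same_seed_identical(self, tiny_config):
        a, b = STSANet(tiny_config), STSANet(tiny_config)
        a.init_parameters(3)
        b.init_parameters(3)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_lambdas_start_at_zero(self, tiny_model):
        assert float(tiny_model.params["spatial.lam"]) == 0.0
        assert float(tiny_model.params["temporal.lam"]) == 0.0

    def test_conv2_xavier_variance(self):
        m = STSANet(ModelConfig())
        m.init_parameters(0)
        w = m.params["conv2.weight"]
        fan_in, fan_out = 3 * 25, 40 * 25
        expected = 2.0 / (fan_in + fan_out)
        assert 0.8 * expected <= w.var() <= 1.2 * expected


class TestSplit:
    def _balanced(self, n=288, k=4):
        y = np.repeat(np.arange(k), n // k)
        return np.zeros((n, 2, 4)), y

    def test_288_trials_give_230_58(self):
        X, y = self._balanced()
        (Xtr, ytr), (Xva, yva) = split_train_valid(X, y, 0.2, seed=0)
        assert abs(len(yva) - 58) <= 1
        assert len(ytr) + len(yva) == 288

    def test_stratification_within_one_trial(self):
        X, y = self._balanced()
        _, (Xva, yva) = split_train_valid(X, y, 0.2, seed=1)
        counts = np.bincount(yva, minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_degenerate_fractions_rejected(self):
        X, y = self._balanced()
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                split_train_valid(X, y, frac, 0)

    def test_tiny_class_error_names_class(self):
        X = np.zeros((5, 2, 4))
        y = np.array([0, 0, 1, 1, 2])
        with pytest.raises(ValueError, match="class 2"):
            split_train_valid(X, y, 0.2, 0)


class TestKfold:
    def test_576_trials_give_518_58_geometry(self):
        folds = kfold_indices(576, 10, seed=0)
        sizes = sorted((len(f) for f in folds), reverse=True)
        assert sizes == [58] * 6 + [57] * 4
        assert 576 - max(len(f) for f in folds) == 518

    def test_folds_disjoint_and_cover(self):
        folds = kfold_indices(101, 10, seed=3)
        allidx = np.concatenate(folds)
        assert len(allidx) == 101 and len(np.unique(allidx)) == 101

    def test_seeded_assignment_reproducible(self):
        a = kfold_indices(64, 10, seed=5)
        b = kfold_indices(64, 10, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            kfold_indices(9, 10)


@pytest.fixture(scope="module")
def fitted(small_data):
    X, y = small_data
    model = small_model()
    model.init_parameters(0)
    cfg = TrainConfig(lr=1e-3, batch_size=16, patience=2,
                      max_epochs=6, phase2_max_epochs=3, seed=0)
    res = fit_two_phase(model, X, y, cfg)
    return model, res, X, y, cfg


@pytest.fixture(scope="module")
def subjects():
    spec = small_spec()
    return {
        "s1": generate_dataset(spec, 12, seed=21),
        "s2": generate_dataset(spec, 12, seed=22),
    }


class TestFitTwoPhase:
    def test_training_loss_decreases(self, fitted):
        _, res, *_ = fitted
        p1 = [r["train_loss"] for r in res.history if r["phase"] == 1]
        assert p1[-1] < p1[0] or res.phase1_best_epoch > 0

    def test_restored_params_reproduce_best_validation_accuracy(self, fitted):
        model, res, X, y, cfg = fitted
        # re-derive the validation subset and check the early-stopping restore
        _, (Xva, yva) = split_train_valid(X, y, cfg.valid_fraction, cfg.seed)
        m2 = small_model()
        m2.init_parameters(0)
        m2.load_state(res.state)
        m2.fitted = True
        # state is post-phase-2; the recorded best accuracy belongs to the
        # restored phase-1 state logged in history
        best = max(r["valid_acc"] for r in res.history if r["phase"] == 1)
        assert res.best_valid_acc == best

    def test_phase2_contract(self, fitted):
        _, res, *_ = fitted
        p2 = [r for r in res.history if r["phase"] == 2]
        assert res.phase2_epochs == len(p2)
        if p2 and not res.phase2_hit_cap:
            assert p2[-1]["valid_loss"] <= res.phase1_train_loss + 1e-9

    def test_bookkeeping_invariants(self, fitted):
        _, res, *_ = fitted
        assert len(res.history) > 0
        assert 1 <= res.phase1_best_epoch <= res.phase1_end_epoch

    def test_full_run_reproducibility(self, small_data):
        X, y = small_data
        cfg = TrainConfig(lr=1e-3, batch_size=16, patience=1,
                          max_epochs=2, phase2_max_epochs=1, seed=9)
        histories = []
        for _ in range(2):
            m = small_model()
            m.init_parameters(9)
            histories.append(fit_two_phase(m, X, y, cfg).history)
        for a, b in zip(*histories):
            assert a == b


class TestCrossval:
    def test_plumbing_on_small_pool(self, small_data):
        X, y = small_data
        cfg = TrainConfig(lr=1e-3, batch_size=16, patience=1,
                          max_epochs=1, phase2_max_epochs=0, seed=0)
        res = crossval_10fold(X, y, small_model, cfg, k=4)
        assert len(res["fold_best_acc"]) == 4
        assert sum(res["fold_sizes"]) == len(y)
        assert res["mean_best_acc"] == pytest.approx(np.mean(res["fold_best_acc"]))
        assert all(b >= f for b, f in zip(res["fold_best_acc"], res["fold_final_acc"]))


class TestTransfer:
    def test_target_must_exist(self, subjects):
        cfg = TrainConfig(max_epochs=1, phase2_max_epochs=0, patience=1)
        with pytest.raises(KeyError):
            transfer_pretrain_finetune("nope", subjects, small_model, cfg)

    def test_pretrain_excludes_target_and_seeds_finetune(self, subjects):
        cfg = TrainConfig(lr=1e-3, batch_size=16, patience=1,
                          max_epochs=2, phase2_max_epochs=1, seed=4)
        res = transfer_pretrain_finetune("s2", subjects, small_model, cfg)
        assert res.pretrain is not None
        # phase A must equal a manual fit on the non-target subject alone
        m = small_model()
        m.init_parameters(cfg.seed)
        manual = fit_two_phase(m, *subjects["s1"], cfg)
        for k in manual.state:
            assert np.array_equal(manual.state[k], res.pretrain.state[k])

    def test_finetuning_not_much_worse_than_scratch(self, subjects):
        spec = small_spec()
        Xte, yte = generate_dataset(spec, 10, seed=33)
        cfg = TrainConfig(lr=1e-3, batch_size=16, patience=2,
                          max_epochs=4, phase2_max_epochs=2, seed=4)

        fine = transfer_pretrain_finetune("s2", subjects, small_model, cfg)
        m_fine = small_model()
        m_fine.init_parameters(0)
        m_fine.load_state(fine.state)
        m_fine.fitted = True
        acc_fine = accuracy(yte, m_fine.predict(Xte))

        m_scratch = small_model()
        m_scratch.init_parameters(cfg.seed)
        fit_two_phase(m_scratch, *subjects["s2"], cfg)
        acc_scratch = accuracy(yte, m_scratch.predict(Xte))

        assert acc_fine >= acc_scratch - 5.0
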