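"""Training tests: loss oracles, freeze discipline, folds, evaluation."""

import math

import numpy as np
import pytest

from seizadapt.model import tail_windows
from seizadapt.network import HDNetwork
from seizadapt.nnet import Adam, params_hash
from seizadapt.training import (
    DomainBatch,
    LabeledBatch,
    TrainConfig,
    adversarial_finetune,
    confusion_table,
    cross_entropy,
    domain_bce,
    evaluate,
    kfold_split,
    one_hot,
    run_adaptation,
    train_discriminator,
    train_phase1,
    train_phase2,
)


class TestLosses:
    def test_cross_entropy_closed_forms(self):
        y = one_hot([0, 1, 2, 3], 4)
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)
        uniform = np.full((4, 4), 0.25)
        assert cross_entropy(y, uniform) == pytest.approx(math.log(4), abs=1e-9)

    def test_cross_entropy_hand_batch(self):
        y = one_hot([0, 1], 2)
        y_hat = np.array([[0.9, 0.1], [0.4, 0.6]])
        expected = -(math.log(0.9) + math.log(0.6)) / 2
        assert cross_entropy(y, y_hat) == pytest.approx(expected, abs=1e-9)

    def test_domain_bce_closed_forms_and_hand_batch(self):
        d = np.array([0, 1, 1])
        assert domain_bce(d, np.array([0.0, 1.0, 1.0])) == pytest.approx(0.0, abs=1e-9)
        assert domain_bce(d, np.full(3, 0.5)) == pytest.approx(math.log(2), abs=1e-9)
        d_hat = np.array([0.2, 0.7, 0.9])
        expected = -(math.log(0.8) + math.log(0.7) + math.log(0.9)) / 3
        assert domain_bce(d, d_hat) == pytest.approx(expected, abs=1e-9)

    def test_losses_nonnegative_on_random_inputs(self, rng):
        for _ in range(100):
            p = rng.dirichlet(np.ones(4), size=8)
            y = one_hot(rng.integers(0, 4, 8), 4)
            assert cross_entropy(y, p) >= 0.0
            d = rng.integers(0, 2, 8)
            assert domain_bce(d, rng.uniform(0.01, 0.99, 8)) >= 0.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            cross_entropy(np.zeros((2, 3)), np.zeros((2, 4)))
        with pytest.raises(ValueError, match="shape mismatch"):
            domain_bce(np.zeros(3), np.zeros(4))


class TestBatches:
    def test_labeled_batch_requires_one_hot_rows(self):
        with pytest.raises(ValueError, match="one-hot"):
            LabeledBatch(np.zeros((2, 3)), np.array([[0.5, 0.2], [1.0, 0.0]]))

    def test_domain_batch_requires_both_domains(self):
        with pytest.raises(ValueError, match="both domains"):
            DomainBatch(np.zeros((2, 3)), np.array([0, 0]))
        with pytest.raises(ValueError, match="must be 0"):
            DomainBatch(np.zeros((2, 3)), np.array([0, 2]))


@pytest.fixture
def tiny_data(tiny_corpus):
    X, y, names = tiny_corpus
    W, wy = tail_windows(X, y)
    return X, y, W, wy


@pytest.fixture(scope="module")
def trained_setup(tiny_spec):
    """A small network actually trained through phases 1-2 on an unnormalized
    corpus, plus a strongly shifted target corpus — the minimal setting in
    which the discriminator has real signal to learn from."""
    from seizadapt.io import CropPolicy, stack_sequences
    from seizadapt.network import HDNConfig
    from seizadapt.synth import DomainShift, generate_corpus

    raw = CropPolicy(normalization="off")
    src = generate_corpus(tiny_spec, 6, seed=99, domain_index=0, policy=raw)
    X, y, _ = stack_sequences(src)
    tgt = generate_corpus(tiny_spec, 6, shift=DomainShift(4.0, 1.0, 2.0),
                          seed=55, domain_index=1, policy=raw)
    tX = np.stack([s.windows for s in tgt])
    cfg = HDNConfig(n_leads=4, n_classes=4, senet_channels=(8, 16),
                    senet_kernels=(7, 5), excitation_hidden=4, f1_hidden=16,
                    hidden_dim=8, gate_depth=2, classifier_hidden=8,
                    discriminator_hidden=8)
    net = HDNetwork(cfg, seed=1)
    tc = TrainConfig(epochs_phase1=40, epochs_phase2=500, disc_max_epochs=100,
                     adversarial_rounds=1, finetune_steps=10, batch_size=16,
                     seed=1)
    W, wy = tail_windows(X, y, per_sequence=3)
    train_phase1(net, W, wy, tc)
    net.fit_feature_norm(X)
    train_phase2(net, X, y, tc)
    return net, X, y, tX, tc


class TestFreezeDiscipline:
    def test_phase1_zero_epochs_is_identity(self, tiny_net, tiny_data, fast_train_config):
        _, _, W, wy = tiny_data
        before = tiny_net.partition_hashes()
        cfg = TrainConfig(**{**fast_train_config.to_dict(), "epochs_phase1": 0})
        train_phase1(tiny_net, W, wy, cfg)
        assert tiny_net.partition_hashes() == before

    def test_phase1_touches_only_g1_f1(self, tiny_net, tiny_data, fast_train_config):
        _, _, W, wy = tiny_data
        before = tiny_net.partition_hashes()
        history = train_phase1(tiny_net, W, wy, fast_train_config)
        after = tiny_net.partition_hashes()
        assert len(history) == fast_train_config.epochs_phase1
        assert after["g1"] != before["g1"] and after["f1"] != before["f1"]
        for frozen in ("g2", "f2", "fd"):
            assert after[frozen] == before[frozen]

    def test_phase1_rejects_single_class(self, tiny_net, tiny_data, fast_train_config):
        _, _, W, wy = tiny_data
        with pytest.raises(ValueError, match="at least 2 classes"):
            train_phase1(tiny_net, W, np.zeros_like(wy), fast_train_config)

    def test_phase2_freezes_g1(self, tiny_net, tiny_data, fast_train_config):
        X, y, W, wy = tiny_data
        train_phase1(tiny_net, W, wy, fast_train_config)
        before = tiny_net.partition_hashes()
        history = train_phase2(tiny_net, X, y, fast_train_config)
        after = tiny_net.partition_hashes()
        assert after["g1"] == before["g1"] and after["f1"] == before["f1"]
        assert after["fd"] == before["fd"]
        assert after["g2"] != before["g2"] and after["f2"] != before["f2"]
        assert len(history["loss"]) == fast_train_config.epochs_phase2

    def test_discriminator_touches_only_fd(self, tiny_net, tiny_data, fast_train_config):
        X, y, _, _ = tiny_data
        feats = tiny_net.sequence_features(X)
        before = tiny_net.partition_hashes()
        train_discriminator(tiny_net, feats[:6], feats[6:], fast_train_config)
        after = tiny_net.partition_hashes()
        for frozen in ("g1", "f1", "g2", "f2"):
            assert after[frozen] == before[frozen]
        assert after["fd"] != before["fd"]

    def test_discriminator_rejects_single_domain(self, tiny_net, tiny_data,
                                                 fast_train_config):
        X, _, _, _ = tiny_data
        feats = tiny_net.sequence_features(X)
        with pytest.raises(ValueError, match="both domains"):
            train_discriminator(tiny_net, feats, feats[:0], fast_train_config)

    def test_finetune_freezes_fd_g1_f1_and_zero_steps_identity(
            self, tiny_net, tiny_data, fast_train_config):
        X, y, _, _ = tiny_data
        feats = tiny_net.sequence_features(X)
        before = tiny_net.partition_hashes()
        adversarial_finetune(tiny_net, feats[:6], y[:6], feats[6:],
                             fast_train_config, steps=0)
        assert tiny_net.partition_hashes() == before
        report = adversarial_finetune(tiny_net, feats[:6], y[:6], feats[6:],
                                      fast_train_config, steps=3)
        after = tiny_net.partition_hashes()
        for frozen in ("g1", "f1", "fd"):
            assert after[frozen] == before[frozen]
        assert len(report) >= 1
        with pytest.raises(ValueError, match="target"):
            adversarial_finetune(tiny_net, feats[:6], y[:6], feats[:0],
                                 fast_train_config, steps=1)

    def test_run_adaptation_zero_rounds_is_identity(self, tiny_net, tiny_data,
                                                    fast_train_config):
        X, y, _, _ = tiny_data
        cfg = TrainConfig(**{**fast_train_config.to_dict(), "adversarial_rounds": 0})
        before = tiny_net.partition_hashes()
        report = run_adaptation(tiny_net, X[:6], y[:6], X[6:], cfg)
        assert tiny_net.partition_hashes() == before
        assert report.changed == {k: False for k in before}

    def test_run_adaptation_changed_flags(self, trained_setup):
        """With a genuinely shifted target and a trained network, adaptation
        updates exactly g2/f2/fd and reports frozen partitions unchanged."""
        net, X, y, tX, tc = trained_setup
        state = {p: m.state_dict() for p, m in net.partitions.items()}
        try:
            report = run_adaptation(net, X, y, tX, tc)
        finally:
            restore = [(net.partitions[p], s) for p, s in state.items()]
            for mod, s in restore:
                mod.load_state_dict(s)
        assert report.changed["g1"] is False and report.changed["f1"] is False
        assert report.changed["g2"] and report.changed["f2"] and report.changed["fd"]
        assert len(report.rows) == tc.adversarial_rounds + 1


class TestAdversarialDirection:
    def test_single_full_batch_step_does_not_decrease_disc_loss(self, trained_setup):
        """One small fine-tune step against a trained, frozen discriminator
        does not reduce that discriminator's loss on the same fixed data."""
        net, X, y, tX, tc = trained_setup
        state = {p: m.state_dict() for p, m in net.partitions.items()}
        try:
            fs, ft = net.sequence_features(X), net.sequence_features(tX)
            train_discriminator(net, fs, ft, tc)
            cfg = TrainConfig(batch_size=2 * len(fs), finetune_lr=1e-4, seed=3)

            def disc_loss():
                p = np.concatenate([net.discriminate_features(fs),
                                    net.discriminate_features(ft)])
                d = np.r_[np.zeros(len(fs)), np.ones(len(ft))]
                return domain_bce(d, p)

            before = disc_loss()
            assert before < np.log(2.0)  # the discriminator actually learned
            adversarial_finetune(net, fs, y, ft, cfg, steps=1)
            assert disc_loss() >= before - 1e-6
        finally:
            for p, s in state.items():
                net.partitions[p].load_state_dict(s)


class TestKFold:
    def test_six_folds_of_twelve_samples(self):
        labels = np.repeat([0, 1], 6)
        folds = kfold_split(labels, k=6, seed=1)
        assert len(folds) == 6
        assert all(len(va) == 2 for _, va in folds)

    def test_folds_partition_the_dataset(self):
        labels = np.repeat([0, 1, 2, 3], 9)
        folds = kfold_split(labels, k=6, seed=2)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val.tolist()) == list(range(36))
        for i, (_, va) in enumerate(folds):
            for j, (_, vb) in enumerate(folds):
                if i != j:
                    assert not set(va) & set(vb)

    def test_stratification_within_one_sample(self):
        labels = np.repeat([0, 1, 2, 3], 12)
        for _, va in kfold_split(labels, k=6, seed=3):
            counts = np.bincount(labels[va], minlength=4)
            assert np.all(np.abs(counts - 2) <= 1)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="exceeds dataset size"):
            kfold_split(np.array([0, 1]), k=6)


class TestEvaluate:
    def test_perfect_predictions_and_constant_predictor(self):
        y = np.repeat([0, 1, 2, 3], 5)
        cm = confusion_table(y, y, ["a", "b", "c", "d"])
        assert np.trace(cm.values) == 20
        assert (np.diag(cm.values) == 5).all()
        cm2 = confusion_table(y, np.zeros_like(y), ["a", "b", "c", "d"])
        assert np.trace(cm2.values) / len(y) == 0.25

    def test_hand_counted_confusion(self):
        y_true = np.array([0, 0, 1, 1, 1])
        y_pred = np.array([0, 1, 1, 1, 0])
        cm = confusion_table(y_true, y_pred, ["n", "s"])
        assert cm.values.tolist() == [[1, 1], [1, 2]]

    def test_empty_set_rejected(self, tiny_net):
        with pytest.raises(ValueError, match="empty"):
            evaluate(tiny_net, np.zeros((0, 8, 4, 32)), np.zeros(0, dtype=int))

    def test_evaluate_is_deterministic(self, tiny_net, tiny_data):
        X, y, _, _ = tiny_data
        a1, cm1 = evaluate(tiny_net, X, y)
        a2, cm2 = evaluate(tiny_net, X, y)
        assert a1 == a2 and cm1.equals(cm2)


def test_phase1_learns_separable_windows(tiny_spec):
    """On a high-SNR 4-class corpus a small front-end reaches >= 0.9 window
    accuracy within 60 epochs at a fixed seed."""
    from seizadapt.io import stack_sequences
    from seizadapt.network import HDNConfig
    from seizadapt.synth import generate_corpus

    seqs = generate_corpus(tiny_spec, 12, seed=5)
    X, y, _ = stack_sequences(seqs)
    W, wy = tail_windows(X, y, per_sequence=3)
    cfg = HDNConfig(n_leads=4, n_classes=4, senet_channels=(8, 16),
                    senet_kernels=(7, 5), excitation_hidden=4, f1_hidden=16,
                    hidden_dim=8, gate_depth=2, classifier_hidden=8,
                    discriminator_hidden=8)
    net = HDNetwork(cfg, seed=1)
    history = train_phase1(net, W, wy, TrainConfig(epochs_phase1=60,
                                                   batch_size=32, seed=1))
    acc = float((net.classify_windows(W).argmax(1) == wy).mean())
    assert acc >= 0.9
    assert history[-1] < history[0]
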