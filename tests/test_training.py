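"""Loss, metrics, ROC/PR, gradient sanity, and the training loop contracts."""

import dataclasses
import math

import numpy as np
import pytest

from spikeprom import seqdata
from spikeprom.layers import Linear
from spikeprom.model import ModelConfig, build
from spikeprom.neurons import NeuronConfig, SpikingNeuronLayer
from spikeprom.seqdata import ValidationError
from spikeprom.training import (ConfusionCounts, TrainConfig, confusion,
                                cross_validate, evaluate, fit, metrics, mse_loss,
                                one_hot_targets, roc_pr_curves)


def pairwise_auc(scores, labels):
    """Brute-force rank statistic: (concordant + ties/2) / (P*N)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMseLoss:
    def test_perfect_fit_zero(self):
        r = np.array([[0.2, 0.8]])
        assert mse_loss(r, r)[0] == 0.0

    def test_worst_case_single_sample(self):
        loss, _ = mse_loss(np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((4, 2)), rng.random((4, 2))
        assert mse_loss(a, b)[0] == pytest.approx(mse_loss(b, a)[0])

    def test_gradient_matches_fd(self, rng):
        r, t = rng.random((3, 2)), rng.random((3, 2))
        loss, g = mse_loss(r, t)
        eps = 1e-6
        rp = r.copy(); rp[1, 0] += eps
        rm = r.copy(); rm[1, 0] -= eps
        fd = (mse_loss(rp, t)[0] - mse_loss(rm, t)[0]) / (2 * eps)
        assert g[1, 0] == pytest.approx(fd, rel=1e-4)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestConfusion:
    def test_simple_tallies(self):
        c = confusion([1, 0], [1, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)
        c = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 2, 2)

    def test_matches_loop_tally(self, rng):
        yt = rng.integers(0, 2, 50)
        yp = rng.integers(0, 2, 50)
        c = confusion(yt, yp)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for a, b in zip(yt, yp):
            key = ("T" if a == b else "F") + ("P" if b == 1 else "N")
            tally[key] += 1
        assert dataclasses.asdict(c) == tally
        assert c.n == 50


class TestMetrics:
    def test_worked_example(self):
        m = metrics(ConfusionCounts(TP=8, TN=9, FP=1, FN=2))
        assert m["Sn"] == pytest.approx(0.8)
        assert m["Sp"] == pytest.approx(0.9)
        assert m["Acc"] == pytest.approx(0.85)
        assert m["Pre"] == pytest.approx(8 / 9)
        assert m["F1"] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))
        assert m["MCC"] == pytest.approx(70 / math.sqrt(9900))

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert all(m[k] == 1.0 for k in ("Sn", "Sp", "Pre", "Acc", "F1", "MCC"))

    def test_label_flip_symmetry(self):
        # flipping both truth and prediction swaps TP<->TN and FP<->FN,
        # hence Sn<->Sp, while MCC magnitude is unchanged
        a = metrics(ConfusionCounts(TP=8, TN=9, FP=1, FN=2))
        b = metrics(ConfusionCounts(TP=9, TN=8, FP=2, FN=1))
        assert a["Sn"] == pytest.approx(b["Sp"])
        assert a["Sp"] == pytest.approx(b["Sn"])
        assert abs(a["MCC"]) == pytest.approx(abs(b["MCC"]))

    def test_degenerate_denominators_report_zero(self):
        m = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=5))
        assert m["Pre"] == 0.0 and m["F1"] == 0.0 and m["MCC"] == 0.0

    def test_order_invariance_through_confusion(self, rng):
        yt = rng.integers(0, 2, 30)
        yp = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        assert metrics(confusion(yt, yp)) == metrics(confusion(yt[perm], yp[perm]))


class TestRocPr:
    def test_perfect_separation(self):
        auc, auprc = roc_pr_curves([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0 and auprc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_pr_curves([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        # quantized scores (k/T rates) exercise tie handling
        scores = rng.integers(0, 10, n) / 9.0
        auc, _ = roc_pr_curves(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_pr_curves([0.1, 0.9], [1, 1])


class TestGradientSanity:
    def test_toy_net_backward_matches_fd(self):
        # one linear weight column into a single (soft) IF neuron over T steps
        rng = np.random.default_rng(0)
        lin = Linear(3, 1, rng, dtype=np.float64)
        neuron = SpikingNeuronLayer(NeuronConfig(surrogate="arctan", alpha=2.0),
                                    soft=True)
        X = rng.random((4, 5, 3))      # T=4 steps, batch 5
        tgt = rng.random((4, 5, 1))

        def loss():
            return float(((neuron.forward(lin.forward(X)) - tgt) ** 2).mean())

        out = neuron.forward(lin.forward(X))
        lin.dW[...] = 0
        g = 2 * (out - tgt) / out.size
        lin.backward(neuron.backward(g))
        eps = 1e-6
        for idx in [(0, 0), (1, 0), (2, 0)]:
            orig = lin.W[idx]
            lin.W[idx] = orig + eps
            lp = loss()
            lin.W[idx] = orig - eps
            lm = loss()
            lin.W[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert lin.dW[idx] == pytest.approx(fd, abs=1e-3, rel=1e-3)

    def test_lif_toy_net_backward_matches_fd(self):
        rng = np.random.default_rng(1)
        lin = Linear(2, 2, rng, dtype=np.float64)
        neuron = SpikingNeuronLayer(
            NeuronConfig(kind="LIF", surrogate="sigmoid", alpha=4.0, tau=2.0),
            soft=True)
        X = rng.random((3, 4, 2)) * 2

        def loss():
            return float(neuron.forward(lin.forward(X)).sum())

        out = neuron.forward(lin.forward(X))
        lin.dW[...] = 0
        lin.backward(neuron.backward(np.ones_like(out)))
        eps = 1e-6
        orig = lin.W[0, 1]
        lin.W[0, 1] = orig + eps
        lp = loss()
        lin.W[0, 1] = orig - eps
        lm = loss()
        lin.W[0, 1] = orig
        assert lin.dW[0, 1] == pytest.approx((lp - lm) / (2 * eps), abs=1e-3, rel=1e-3)


@pytest.fixture
def micro_cfg():
    return ModelConfig(L=16, T=3, channels=4, K=3, heads=2, dropout_p=0.2)


@pytest.fixture
def micro_records():
    spec = seqdata.SyntheticSpec(
        n_pos=24, n_neg=24, length=16,
        motifs=[seqdata.Motif("TATAAT", 4, sub_prob=0.05)], seed=2)
    return seqdata.generate_synthetic(spec)


class TestFit:
    def test_zero_epochs_is_noop(self, micro_cfg, micro_records):
        net = build(micro_cfg, seed=0)
        before = {k: v.copy() for k, (v, _) in net.params().items()}
        history = fit(net, micro_records, None, TrainConfig(epochs=0, seed=0))
        assert history == []
        for k, (v, _) in net.params().items():
            assert np.array_equal(before[k], v)

    def test_determinism(self, micro_cfg, micro_records):
        cfg = TrainConfig(epochs=2, seed=5, batch_size=8)
        nets = []
        for _ in range(2):
            net = build(micro_cfg, seed=3)
            fit(net, micro_records[:32], micro_records[32:], dataclasses.replace(cfg))
            nets.append({k: v.copy() for k, (v, _) in net.params().items()})
        for k in nets[0]:
            assert np.array_equal(nets[0][k], nets[1][k])

    def test_empty_training_set_rejected(self, micro_cfg):
        with pytest.raises(ValidationError):
            fit(build(micro_cfg, seed=0), [], None, TrainConfig(epochs=1))

    def test_history_schema(self, micro_cfg, micro_records):
        net = build(micro_cfg, seed=0)
        history = fit(net, micro_records[:32], micro_records[32:],
                      TrainConfig(epochs=2, seed=0, batch_size=8))
        assert [h["epoch"] for h in history] == [0, 1]
        for h in history:
            assert set(h) == {"epoch", "train_loss", "val_loss", "val_acc"}


class TestCrossValidate:
    def test_fold_accounting_and_means(self, micro_cfg, micro_records):
        cfg = TrainConfig(epochs=1, seed=0, batch_size=16)
        result = cross_validate(micro_records, lambda s: build(micro_cfg, seed=s),
                                cfg, K=4, seed=0)
        assert len(result["folds"]) == 4
        for key, val in result["mean"].items():
            per_fold = [f[key] for f in result["folds"]]
            assert val == pytest.approx(float(np.mean(per_fold)))

    def test_heldout_sets_partition_dataset(self, micro_records):
        folds = seqdata.kfold_split([r.label for r in micro_records], 4, seed=0)
        seen = np.concatenate([folds.members(k) for k in range(4)])
        assert sorted(seen.tolist()) == list(range(len(micro_records)))


class TestEvaluate:
    def test_report_keys_and_ranges(self, micro_cfg, micro_records):
        net = build(micro_cfg, seed=0)
        report = evaluate(net, micro_records)
        for key in ("Sn", "Sp", "Pre", "Acc", "F1", "AUC", "AUPRC"):
            assert 0.0 <= report[key] <= 1.0
        assert -1.0 <= report["MCC"] <= 1.0

    def test_one_hot_targets(self):
        t = one_hot_targets(np.array([0, 1, 1]))
        assert t.tolist() == [[1, 0], [0, 1], [0, 1]]
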