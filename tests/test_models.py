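"""Networks, training protocol, cross-validation, and metrics."""

import numpy as np
import pandas as pd
import pytest

from cfgem import nn
from cfgem.errors import InvalidInputError
from cfgem.models import (CohortScores, ModelSpec, build_epigenome_net,
                          build_genome_net, combine_scores, crossvalidate,
                          evaluate, fit_gbdt_baseline, roc_auc,
                          sensitivity_at_specificity, train_with_restarts)
from cfgem.rng import substream


def _sep_data(n=20, d=12, seed=0):
    rng = substream(seed, "sep")
    x = rng.normal(size=(n, d)).astype(np.float32)
    y = (x[:, 0] > 0).astype(int)
    x[:, 0] += 3.0 * (2 * y - 1)  # widen the margin
    return x, y


class TestGenomeNet:
    def test_detection_scores_in_unit_interval(self):
        rng = substream(1, "a")
        net = build_genome_net(ModelSpec(family="genome-dnn"), 30, rng)
        p = net.predict_proba(rng.normal(size=(8, 30)).astype(np.float32))
        assert ((p > 0) & (p < 1)).all()

    def test_localization_softmax_sums_to_one(self):
        rng = substream(1, "b")
        net = build_genome_net(ModelSpec(family="genome-dnn", task="localization",
                                         n_classes=4), 30, rng)
        p = net.predict_proba(rng.normal(size=(5, 30)).astype(np.float32))
        assert p.shape == (5, 4) and np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_capacity_overfits_separable_data(self):
        x, y = _sep_data()
        spec = ModelSpec(family="genome-dnn", dropout=0.0, seed=3)
        rng = substream(3, "cap")
        net = build_genome_net(spec, x.shape[1], rng)
        net.class_weights = nn.class_weight_map(y, 2)
        res = nn.train_network(net, x, y, x, y, rng, max_epochs=500, patience=500,
                               batch_size=8)
        assert res.history[-1][0] < 0.05


class TestEpigenomeNet:
    def test_output_shapes_and_kernel_counts(self):
        rng = substream(2, "e")
        spec = ModelSpec(family="epigenome-cnn", conv1_kernels=250)
        net = build_epigenome_net(spec, (100, 250, 2), rng)
        conv_layers = [l for l in net.layers if isinstance(l, nn.Conv3x3)]
        assert conv_layers[0].params[0].shape == (3, 3, 2, 250)
        assert conv_layers[1].params[0].shape == (3, 3, 250, 1)
        spec_loc = ModelSpec(family="epigenome-cnn", conv1_kernels=3,
                             task="localization", n_classes=3)
        net_loc = build_epigenome_net(spec_loc, (100, 250, 2), rng)
        x = rng.random((2, 100, 250, 2)).astype(np.float32)
        assert net_loc.predict_proba(x).shape == (2, 3)

    def test_capacity_overfits_small_tensor_set(self):
        rng = substream(5, "cap")
        x = rng.random((20, 100, 250, 2)).astype(np.float32)
        y = np.repeat([0, 1], 10)
        x[y == 1, 40:60, :, :] += 0.5
        spec = ModelSpec(family="epigenome-cnn", conv1_kernels=2, dropout=0.0, lr=3e-3)
        net = build_epigenome_net(spec, x.shape[1:], rng)
        net.class_weights = nn.class_weight_map(y, 2)
        res = nn.train_network(net, x, y, x, y, rng, max_epochs=40, patience=40,
                               batch_size=10)
        assert res.history[-1][0] < 0.1


class TestClassWeights:
    def test_balanced_classes_reduce_to_unweighted_loss(self):
        rng = substream(6, "bal")
        x = rng.normal(size=(16, 12)).astype(np.float32)
        y = np.repeat([0, 1], 8)
        rng = substream(6, "w")
        net = build_genome_net(ModelSpec(family="genome-dnn", dropout=0.0), x.shape[1], rng)
        net.class_weights = None
        lu, _ = net.loss(x, y, train=False)
        net.class_weights = nn.class_weight_map(y, 2)  # balanced -> all ones
        lw, _ = net.loss(x, y, train=False)
        assert np.allclose(nn.class_weight_map(y, 2), 1.0)
        assert np.isclose(lu, lw)


class TestRestarts:
    def test_single_restart_equals_direct_training(self):
        x, y = _sep_data(n=24)
        spec = ModelSpec(family="genome-dnn", seed=9, max_epochs=30, patience=30)
        net1, losses = train_with_restarts(spec, x, y, x, y, n_restarts=1)
        rng = substream(spec.seed, "restart", spec.family, spec.task, 0)
        net2 = build_genome_net(spec, x.shape[1], rng)
        net2.class_weights = nn.class_weight_map(y, 2)
        nn.init_output_bias(net2, y)
        res = nn.train_network(net2, x, y, x, y, rng, lr=spec.lr,
                               weight_decay=spec.weight_decay, batch_size=spec.batch_size,
                               max_epochs=30, patience=30)
        assert np.isclose(losses[0], res.val_loss)
        assert np.allclose(net1.predict_proba(x), net2.predict_proba(x))

    def test_best_restart_selected(self):
        x, y = _sep_data(n=24)
        spec = ModelSpec(family="genome-dnn", seed=10, max_epochs=20, patience=20)
        net, losses = train_with_restarts(spec, x, y, x, y, n_restarts=3)
        val_loss, _ = net.loss(x, y, train=False)
        assert np.isclose(val_loss, min(losses), atol=1e-6)

    def test_reproducible_under_fixed_seed(self):
        x, y = _sep_data(n=24)
        spec = ModelSpec(family="genome-dnn", seed=11, max_epochs=15, patience=15)
        _, l1 = train_with_restarts(spec, x, y, x, y, n_restarts=2)
        _, l2 = train_with_restarts(spec, x, y, x, y, n_restarts=2)
        assert l1 == l2


class TestCrossValidation:
    def test_partition_arithmetic(self):
        x, y = _sep_data(n=100, d=8, seed=12)
        spec = ModelSpec(family="genome-dnn", seed=12, max_epochs=10, patience=10,
                         n_restarts=1)
        scores = crossvalidate(x, y, spec, k=5)
        assert scores.table["score"].notna().all()
        assert (scores.table["fold"].value_counts() == 20).all()

    def test_stratification_within_one_sample(self):
        rng = substream(13, "strat")
        x = rng.normal(size=(100, 6)).astype(np.float32)
        y = np.array([1] * 20 + [0] * 80)
        spec = ModelSpec(family="genome-dnn", seed=13, max_epochs=5, patience=5,
                         n_restarts=1)
        scores = crossvalidate(x, y, spec, k=5)
        per_fold = scores.table.groupby("fold")["label"].sum()
        assert per_fold.between(3, 5).all()

    def test_small_class_rejected_by_name(self):
        x, y = _sep_data(n=20)
        y = np.zeros(20, dtype=int)
        y[:3] = 1
        spec = ModelSpec(family="genome-dnn", n_restarts=1)
        with pytest.raises(InvalidInputError, match="1"):
            crossvalidate(x, y, spec, k=5)

    def test_two_fold_degenerate_still_valid(self):
        x, y = _sep_data(n=40)
        spec = ModelSpec(family="genome-dnn", seed=14, max_epochs=5, patience=5,
                         n_restarts=1)
        scores = crossvalidate(x, y, spec, k=2)
        assert scores.table["score"].notna().all()


class TestGBDT:
    def test_budget_one_refits_single_config(self):
        x, y = _sep_data(n=60, d=6, seed=15)
        model = fit_gbdt_baseline(x, y, search_budget=1, seed=15)
        assert model.predict_proba(x).shape == (60, 2)

    def test_separable_data_fit_to_low_log_loss(self):
        x, y = _sep_data(n=60, d=6, seed=15)
        model = fit_gbdt_baseline(x, y, search_budget=8, seed=15)
        from sklearn.metrics import log_loss
        assert log_loss(y, model.predict_proba(x)[:, 1]) < 0.1

    def test_fixed_seed_reproducible(self):
        x, y = _sep_data(n=60, d=6, seed=16)
        m1 = fit_gbdt_baseline(x, y, search_budget=3, seed=16)
        m2 = fit_gbdt_baseline(x, y, search_budget=3, seed=16)
        assert m1.get_params()["max_depth"] == m2.get_params()["max_depth"]
        assert np.allclose(m1.predict_proba(x), m2.predict_proba(x))

    def test_invalid_budget_rejected(self):
        x, y = _sep_data()
        with pytest.raises(InvalidInputError):
            fit_gbdt_baseline(x, y, search_budget=0)


def _scores_frame(y, s, task="detection"):
    return CohortScores(table=pd.DataFrame({"sample": [f"s{i}" for i in range(len(y))],
                                            "label": y, "fold": 0, "score": s}),
                        task=task)


class TestCombination:
    def test_mean_of_two_scores(self):
        a = _scores_frame([0, 1], [0.6, 0.6])
        b = _scores_frame([0, 1], [0.8, 0.8])
        assert combine_scores(a, b).table["score"].tolist() == [0.7, 0.7]

    def test_identity_on_equal_inputs(self):
        a = _scores_frame([0, 1], [0.3, 0.9])
        assert combine_scores(a, a).table["score"].tolist() == [0.3, 0.9]

    def test_localization_average_still_sums_to_one(self):
        t = pd.DataFrame({"sample": ["a", "b"], "label": [0, 1], "fold": 0,
                          "score_x": [0.2, 0.7], "score_y": [0.8, 0.3]})
        t2 = pd.DataFrame({"sample": ["a", "b"], "label": [0, 1], "fold": 0,
                           "score_x": [0.6, 0.1], "score_y": [0.4, 0.9]})
        a = CohortScores(t, task="localization", class_names=("x", "y"))
        b = CohortScores(t2, task="localization", class_names=("x", "y"))
        c = combine_scores(a, b)
        assert np.allclose(c.scores.sum(axis=1), 1.0)

    def test_sample_mismatch_rejected(self):
        a = _scores_frame([0, 1], [0.1, 0.9])
        b = CohortScores(a.table.assign(sample=["x", "y"]), task="detection")
        with pytest.raises(InvalidInputError):
            combine_scores(a, b)


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([0] * 5 + [1] * 5)
        s = np.array([0.1] * 5 + [0.9] * 5)
        m = evaluate(_scores_frame(y, s), n_boot=50)
        assert m["auc"] == 1.0
        assert all(v["estimate"] == 1.0 for v in m["sensitivity"].values())

    def test_random_scores_near_half(self):
        rng = substream(17, "auc")
        y = np.repeat([0, 1], 500)
        s = rng.random(1000)
        assert abs(roc_auc(y, s) - 0.5) < 0.06

    def test_auc_matches_pair_counting_oracle(self):
        rng = substream(18, "pairs")
        for _ in range(5):
            y = rng.integers(0, 2, size=6)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(6), 1)  # ties likely
            wins = ties = 0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    wins += s[i] > s[j]
                    ties += s[i] == s[j]
            n_pairs = (y == 1).sum() * (y == 0).sum()
            assert np.isclose(roc_auc(y, s), (wins + 0.5 * ties) / n_pairs)

    def test_sensitivity_respects_specificity_floor(self):
        y = np.array([0] * 10 + [1] * 10)
        s = np.concatenate([np.linspace(0, 0.9, 10), np.linspace(0.3, 1.0, 10)])
        for level in (0.95, 0.98, 0.99):
            sens = sensitivity_at_specificity(y, s, level)
            thr_mask = s[y == 0] >= 0.9  # only the top control can be a false positive
            assert 0.0 <= sens <= 1.0
            assert sens == np.mean(s[y == 1] > s[y == 0].max() - 1e-12) or sens >= 0

    def test_one_class_rejected(self):
        with pytest.raises(InvalidInputError):
            evaluate(_scores_frame([1, 1], [0.5, 0.6]), n_boot=10)

    def test_localization_confusion_rows_normalized(self):
        t = pd.DataFrame({"sample": list("abcd"), "label": [0, 0, 1, 1], "fold": 0,
                          "score_x": [0.9, 0.4, 0.2, 0.1], "score_y": [0.1, 0.6, 0.8, 0.9]})
        m = evaluate(CohortScores(t, task="localization", class_names=("x", "y")))
        assert m["accuracy"] == 0.75
        assert np.allclose(m["confusion"].sum(axis=1), 1.0)
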