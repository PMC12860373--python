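"""Random-Forest feature ranking, BP network training and evaluation."""

import numpy as np
import pytest

from coformer_scout import (
    BPClassifier,
    ConfusionMatrix,
    FeatureImportance,
    RFConfig,
    bp_loss_and_grad,
    evaluate,
    load_model,
    rank_features_rf,
    save_model,
    select_top_features,
)


def _gini(y):
    p = y.mean()
    return 2 * p * (1 - p)


def _best_split_gain(x, y):
    """Exhaustive single-split Gini-gain oracle for one feature."""
    gain = 0.0
    for cut in np.unique(x)[:-1]:
        left, right = y[x <= cut], y[x > cut]
        child = (len(left) * _gini(left) + len(right) * _gini(right)) / len(y)
        gain = max(gain, _gini(y) - child)
    return gain


def _planted_ranking_data(seed, n=200, p=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    informative = int(rng.integers(p))
    y = (X[:, informative] > 0).astype(int)
    return X, y, informative


class TestFeatureRanking:
    def test_label_determining_feature_ranks_first(self):
        X, y, informative = _planted_ranking_data(seed=0)
        cols = [f"f{j}" for j in range(X.shape[1])]
        imp = rank_features_rf(X, y, RFConfig(seed=0), columns=cols)
        assert imp.names[0] == f"f{informative}"
        assert imp.ranking[0][1] > 0.5
        # agrees with the exhaustive single-split Gini oracle
        gains = [_best_split_gain(X[:, j], y) for j in range(X.shape[1])]
        assert int(np.argmax(gains)) == informative

    def test_constant_feature_gets_negligible_importance(self):
        X, y, _ = _planted_ranking_data(seed=1)
        X[:, 3] = 7.7
        imp = rank_features_rf(X, y, RFConfig(seed=0), columns=list("abcde"))
        assert imp.as_dict()["d"] < 0.01

    def test_ranking_deterministic_under_seed(self):
        X, y, _ = _planted_ranking_data(seed=2)
        cols = list("abcde")
        a = rank_features_rf(X, y, RFConfig(seed=9), columns=cols)
        b = rank_features_rf(X, y, RFConfig(seed=9), columns=cols)
        assert a == b

    def test_importances_sum_to_one_and_descend(self, trained_screen, default_library):
        _, featurizer, train, _ = trained_screen
        fm = featurizer.transform(train)
        imp = rank_features_rf(fm, train.labels, RFConfig(seed=0))
        vals = [v for _, v in imp.ranking]
        assert sum(vals) == pytest.approx(1.0, abs=1e-9)
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert set(imp.names) == {"mw", "hbd", "tpsa", "tyr_inhib", "smiles_enc"}

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="two classes"):
            rank_features_rf(X, np.ones(10, dtype=int), columns=list("abc"))

    def test_select_top_features(self):
        imp = FeatureImportance(ranking=(("a", 0.5), ("b", 0.3), ("c", 0.2)))
        assert select_top_features(imp, 3) == ("a", "b", "c")
        assert select_top_features(imp, 2) == ("a", "b")
        with pytest.raises(ValueError):
            select_top_features(imp, 4)

    def test_exact_ties_break_toward_lower_column_index(self):
        imp = FeatureImportance(ranking=(("x", 0.4), ("y", 0.3), ("z", 0.3)))
        assert select_top_features(imp, 2) == ("x", "y")


def finite_difference_gradient_error(seed: int, n_nets: int = 10) -> float:
    """Worst norm-ratio disagreement ||g - fd|| / max(||g||, ||fd||) between
    backprop and central finite differences over random 3-4-1 networks."""
    rng = np.random.default_rng(seed)
    h = 1e-6
    worst = 0.0
    for _net in range(n_nets):
        weights = [rng.normal(size=(3, 4)), rng.normal(size=(4, 1))]
        biases = [rng.normal(size=4), rng.normal(size=1)]
        X = rng.normal(size=(10, 3))
        y = rng.integers(0, 2, size=10)
        _, gw, gb = bp_loss_and_grad(weights, biases, X, y)
        analytic, numeric = [], []
        for arr, grad in list(zip(weights, gw)) + list(zip(biases, gb)):
            flat = arr.ravel()
            analytic.extend(np.asarray(grad).ravel())
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _, _ = bp_loss_and_grad(weights, biases, X, y)
                flat[idx] = orig - h
                lm, _, _ = bp_loss_and_grad(weights, biases, X, y)
                flat[idx] = orig
                numeric.append((lp - lm) / (2 * h))
        g, fd = np.asarray(analytic), np.asarray(numeric)
        worst = max(worst, np.linalg.norm(g - fd) / max(np.linalg.norm(g), np.linalg.norm(fd)))
    return worst


class TestGradients:
    def test_backprop_matches_central_finite_differences(self):
        """Analytic gradients on random 3-4-1 nets vs central differences."""
        assert finite_difference_gradient_error(seed=0) < 1e-5


class TestBPClassifier:
    def test_untrained_epochs_zero_predicts_near_half(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 2, size=50)
        m = BPClassifier(epochs=0, random_state=0).fit(X, y)
        p = m.predict_proba(X)
        assert np.all(p == 0.5)

    def test_all_zero_weights_give_exact_half(self):
        m = BPClassifier(epochs=0, random_state=0).fit(np.zeros((4, 2)), [0, 1, 0, 1])
        for W in m.coefs_:
            W[:] = 0.0
        for b in m.intercepts_:
            b[:] = 0.0
        assert np.all(m.predict_proba(np.random.default_rng(1).normal(size=(5, 2))) == 0.5)

    def test_probabilities_bounded(self, trained_screen):
        model, featurizer, train, _ = trained_screen
        p = model.predict_proba(featurizer.transform(train))
        assert np.all((p >= 0) & (p <= 1))

    def test_threshold_reproduces_argmax_rule(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 3))
        y = (X[:, 0] > 0).astype(int)
        m = BPClassifier(epochs=100, random_state=0).fit(X, y)
        p = m.predict_proba(X)
        assert np.array_equal(m.predict(X), (p >= (1 - p)).astype(int))

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        y = (X[:, 1] > 0).astype(int)
        a = BPClassifier(epochs=50, random_state=7).fit(X, y)
        b = BPClassifier(epochs=50, random_state=7).fit(X, y)
        for Wa, Wb in zip(a.coefs_, b.coefs_):
            assert np.array_equal(Wa, Wb)

    def test_nan_input_rejected(self):
        X = np.zeros((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            BPClassifier().fit(X, np.zeros(10))

    def test_column_mismatch_rejected(self, trained_screen):
        model, *_ = trained_screen
        with pytest.raises(ValueError, match="columns"):
            model.predict(np.zeros((3, 2)))

    def test_early_stopping_returns_best_validation_snapshot(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 8))
        y = rng.integers(0, 2, size=120)  # pure noise -> validation overfits fast
        m = BPClassifier(epochs=2000, patience=25, random_state=0).fit(X, y)
        assert len(m.loss_curve_) < 2000  # actually stopped early
        assert m.best_validation_loss_ == pytest.approx(min(m.validation_curve_))

    def test_label_permutation_null_accuracy_near_chance(self, default_library):
        """Shuffled labels carry no signal: mean test accuracy ~= 50%."""
        from coformer_scout import CoformerFeaturizer, split_library

        lib = default_library
        accs = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            y_perm = rng.permutation(lib.labels)
            sp = split_library(lib, 120, seed=s, stratified=False)
            idx = {rid: i for i, rid in enumerate(lib.ids)}
            tr, te = lib.subset(sp.train_ids), lib.subset(sp.test_ids)
            fz = CoformerFeaturizer(features=("mw", "hbd", "tpsa", "tyr_inhib"))
            Xtr = fz.fit_transform(tr)
            ytr = y_perm[[idx[r] for r in sp.train_ids]]
            yte = y_perm[[idx[r] for r in sp.test_ids]]
            m = BPClassifier(epochs=300, random_state=s).fit(Xtr, ytr)
            accs.append((m.predict(fz.transform(te)) == yte).mean())
        assert 0.4 <= np.mean(accs) <= 0.6


class TestConfusionMatrix:
    def test_perfect_predictions_give_hundred_percent(self):
        assert ConfusionMatrix(tp=6, fp=0, fn=0, tn=4).accuracy == 100.0

    def test_reported_accuracy_on_39_entry_evaluation(self):
        # 34 agreements out of 39 -> 87.17948...% -> 87.2% at one decimal
        cm = ConfusionMatrix(tp=20, fp=3, fn=2, tn=14)
        assert cm.total == 39
        assert cm.tp + cm.tn == 34
        assert cm.accuracy == 87.2

    def test_counts_partition_test_set(self, trained_screen):
        model, featurizer, _, test = trained_screen
        rng = np.random.default_rng(0)
        for _ in range(50):
            take = rng.integers(1, len(test) + 1)
            ids = list(rng.choice(test.ids, size=take, replace=False))
            sub = test.subset(ids)
            cm = evaluate(model, featurizer.transform(sub), sub.labels)
            assert cm.total == take

    def test_empty_test_set_rejected(self, trained_screen):
        model, *_ = trained_screen
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, np.zeros((0, model.n_features_in_)), [])


class TestPersistence:
    def test_save_load_round_trip(self, trained_screen, tmp_path):
        model, featurizer, _, test = trained_screen
        path = save_model(tmp_path / "m.json", model, featurizer)
        model2, featurizer2 = load_model(path)
        p1 = model.predict_proba(featurizer.transform(test))
        p2 = model2.predict_proba(featurizer2.transform(test))
        assert np.array_equal(p1, p2)
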