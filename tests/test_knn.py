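import numpy as np
import pytest

from mfbrain import FEATURE_NAMES, LabeledDataset, evaluate_split, fit, predict
from mfbrain.knn import load_model, predict_batch, save_model

N_FEAT = len(FEATURE_NAMES)


def _emb(vals):
    """Embed 1-D toy coordinates as 10 perfectly correlated features, so
    standardized distances are monotone in the 1-D separation."""
    vals = np.asarray(vals, dtype=float).ravel()
    return np.outer(vals, np.arange(1.0, N_FEAT + 1))


def brute_force_knn(x_train, y_train, query, k):
    """Independent oracle: full sort of (distance, index), majority vote,
    ties by nearest among tied classes."""
    d = [(float(np.linalg.norm(row - query)), i) for i, row in enumerate(x_train)]
    d.sort()
    top = d[:k]
    counts = {}
    for _, i in top:
        counts[y_train[i]] = counts.get(y_train[i], 0) + 1
    best = max(counts.values())
    tied = {lab for lab, c in counts.items() if c == best}
    for _, i in top:
        if y_train[i] in tied:
            return y_train[i]
    raise AssertionError


class TestFitValidation:
    def test_k_exceeding_rows_rejected(self):
        data = LabeledDataset(_emb([0.0, 1.0]), np.array(["a", "b"]))
        with pytest.raises(ValueError):
            fit(data, k=3)

    def test_constant_feature_rejected_by_name(self):
        x = _emb([0.0, 1.0, 2.0])
        x[:, 4] = 7.7
        with pytest.raises(ValueError, match=FEATURE_NAMES[4]):
            fit(LabeledDataset(x, np.array(["a", "b", "a"])), k=1)

    def test_k1_training_points_classify_as_themselves(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, N_FEAT))
        y = np.array(list("aabbccaabbcc"))
        model = fit(LabeledDataset(x, y), k=1)
        labels, _ = predict_batch(model, x)
        np.testing.assert_array_equal(labels, y)

    def test_single_class_training(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, N_FEAT))
        model = fit(LabeledDataset(x, np.array(["only"] * 5)), k=3)
        label, votes = predict(model, rng.normal(size=N_FEAT))
        assert label == "only" and votes == {"only": 1.0}


class TestPredict:
    def test_exact_training_point_k1(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, N_FEAT))
        y = np.array(["a", "b", "c", "a", "b", "c"])
        model = fit(LabeledDataset(x, y), k=1)
        label, votes = predict(model, x[3])
        assert label == "a" and votes["a"] == 1.0

    def test_majority_vote_fractions(self):
        # 3 nearest at 1-D distances 1 < 2 < 3 labeled A, B, B -> B with 2/3
        base = _emb([100.0, 1.0, 2.0, 3.0])
        y = np.array(["Q", "A", "B", "B"])  # row 0 is a far filler class
        model = fit(LabeledDataset(base, y), k=3)
        label, votes = predict(model, _emb([0.5])[0])
        assert label == "B"
        assert votes["A"] == pytest.approx(1 / 3)
        assert votes["B"] == pytest.approx(2 / 3)

    def test_vote_tie_broken_by_nearest(self):
        model = fit(LabeledDataset(_emb([0.0, 1.0, 10.0]), np.array(["A", "B", "C"])), k=2)
        # query at 0.1: nearest A, then B -> tie at 1 vote each -> A
        label, _ = predict(model, _emb([0.1])[0])
        assert label == "A"

    def test_non_finite_query_rejected(self):
        model = fit(LabeledDataset(_emb([0.0, 1.0]), np.array(["a", "b"])), k=1)
        bad = np.full(N_FEAT, np.nan)
        with pytest.raises(ValueError):
            predict(model, bad)


class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_brute_force_on_random_instances(self, k):
        rng = np.random.default_rng(42)
        for _ in range(67):
            n = int(rng.integers(k + 1, 50))
            x = rng.normal(size=(n, N_FEAT))
            y = np.array([str(c) for c in rng.integers(0, 3, n)])
            if len(set(y)) < 2:
                y[0] = "extra"
            model = fit(LabeledDataset(x, y), k=k)
            query = rng.normal(size=N_FEAT)
            z = (x - model.feature_mean) / model.feature_sd
            zq = (query - model.feature_mean) / model.feature_sd
            expected = brute_force_knn(z, y, zq, k)
            label, _ = predict(model, query)
            assert label == expected

    def test_matches_sklearn_binary_distinct_distances(self):
        sklearn = pytest.importorskip("sklearn.neighbors")
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(8, 40))
            x = rng.normal(size=(n, N_FEAT))
            y = np.array([str(c) for c in rng.integers(0, 2, n)])
            if len(set(y)) < 2:
                y[0] = "1" if y[1] == "0" else "0"
            model = fit(LabeledDataset(x, y), k=3)
            z = (x - model.feature_mean) / model.feature_sd
            clf = sklearn.KNeighborsClassifier(n_neighbors=3).fit(z, y)
            queries = rng.normal(size=(5, N_FEAT))
            zq = (queries - model.feature_mean) / model.feature_sd
            ours, _ = predict_batch(model, queries)
            np.testing.assert_array_equal(ours, clf.predict(zq))

    def test_row_permutation_invariance_distinct_distances(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(20, N_FEAT))
        y = np.array([str(c) for c in rng.integers(0, 3, 20)])
        query = rng.normal(size=N_FEAT)
        perm = rng.permutation(20)
        l1, _ = predict(fit(LabeledDataset(x, y), k=5), query)
        l2, _ = predict(fit(LabeledDataset(x[perm], y[perm]), k=5), query)
        assert l1 == l2

    def test_affine_feature_rescaling_invariance(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=(30, N_FEAT))
        y = np.array([str(c) for c in rng.integers(0, 2, 30)])
        queries = rng.normal(size=(10, N_FEAT))
        scaled = x.copy()
        scaled[:, 2] = 50.0 * scaled[:, 2] - 7.0
        qs = queries.copy()
        qs[:, 2] = 50.0 * qs[:, 2] - 7.0
        a, _ = predict_batch(fit(LabeledDataset(x, y), k=3), queries)
        b, _ = predict_batch(fit(LabeledDataset(scaled, y), k=3), qs)
        np.testing.assert_array_equal(a, b)


class TestEvaluateSplit:
    def test_separable_classes_reach_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        blocks, labels = [], []
        for i, c in enumerate(["a", "b", "c"]):
            blocks.append(rng.normal(10.0 * i, 0.1, size=(20, N_FEAT)))
            labels += [c] * 20
        data = LabeledDataset(np.vstack(blocks), np.array(labels))
        res = evaluate_split(data, 12, 8, k=3, n_runs=3, seed=0)
        assert res.mean_accuracy == 100.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, N_FEAT))
        y = np.array(["a", "b"] * 20)
        data = LabeledDataset(x, y)
        r1 = evaluate_split(data, 10, 5, k=3, n_runs=1, seed=7)
        r2 = evaluate_split(data, 10, 5, k=3, n_runs=1, seed=7)
        assert r1.per_run == r2.per_run

    def test_insufficient_rows_rejected(self):
        data = LabeledDataset(np.random.default_rng(0).normal(size=(6, N_FEAT)),
                              np.array(["a"] * 3 + ["b"] * 3))
        with pytest.raises(ValueError):
            evaluate_split(data, 3, 1, k=1, n_runs=1, seed=0)


def test_model_text_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    x = rng.normal(size=(10, N_FEAT))
    y = np.array(["a", "b"] * 5)
    model = fit(LabeledDataset(x, y), k=3)
    path = tmp_path / "model.tsv"
    save_model(model, path)
    loaded = load_model(path)
    queries = rng.normal(size=(5, N_FEAT))
    a, va = predict_batch(model, queries)
    b, vb = predict_batch(loaded, queries)
    np.testing.assert_array_equal(a, b)
    np.testing.assert_allclose(va.to_numpy(), vb.to_numpy())
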