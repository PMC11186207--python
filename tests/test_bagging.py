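"""PU bagging: OOB vote bookkeeping, score formula, classifier contract."""

import numpy as np
import pytest

import puconfide as pc
from puconfide.bagging import SingleClassError, fast_svc_rbf_fit_predict, svc_rbf_fit_predict


class RecordingClassifier:
    """Mock classifier that logs calls and predicts from the first feature."""

    def __init__(self):
        self.calls = []

    def __call__(self, train_X, train_y, test_X, random_state=0):
        if np.unique(train_y).size < 2:
            raise SingleClassError("single class")
        self.calls.append((train_X.shape[0], test_X.shape[0]))
        return (test_X[:, 0] > 0).astype(np.int8)


class TestClassifierContract:
    def test_separable_prediction(self):
        train_X = np.array([[1.0, 1.0], [2.0, 1.5], [-1.0, -1.0], [-2.0, -0.5]])
        train_y = np.array([1, 1, 0, 0])
        for clf in (svc_rbf_fit_predict, fast_svc_rbf_fit_predict):
            pred = clf(train_X, train_y, np.array([[1.5, 1.2], [-1.5, -0.8]]))
            assert list(pred) == [1, 0]

    def test_single_class_raises(self):
        X = np.random.default_rng(0).standard_normal((6, 3))
        for clf in (svc_rbf_fit_predict, fast_svc_rbf_fit_predict):
            with pytest.raises(SingleClassError):
                clf(X, np.ones(6), X)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X, y = rng.standard_normal((20, 4)), rng.integers(0, 2, 20)
        Xt = rng.standard_normal((10, 4))
        a = fast_svc_rbf_fit_predict(X, y, Xt, random_state=3)
        b = fast_svc_rbf_fit_predict(X, y, Xt, random_state=3)
        assert np.array_equal(a, b)

    def test_fast_path_matches_public_svc_exactly(self):
        # the direct-libsvm path must agree with sklearn.svm.SVC defaults
        # prediction-for-prediction on randomized instances
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(8, 50))
            p = int(rng.integers(2, 60))
            X = rng.standard_normal((n, p))
            y = rng.integers(0, 2, n)
            if np.unique(y).size < 2:
                continue
            Xt = rng.standard_normal((20, p))
            assert np.array_equal(
                svc_rbf_fit_predict(X, y, Xt), fast_svc_rbf_fit_predict(X, y, Xt)
            )


class TestBaggingScores:
    def test_score_is_votes_over_counts(self, small_pu_dataset):
        res = pc.pu_bagging_scores(small_pu_dataset, pc.BaggingConfig(n_bootstraps=25, seed=3))
        seen = res.oob_counts > 0
        assert np.allclose(res.scores[seen], res.positive_votes[seen] / res.oob_counts[seen])
        assert np.all(res.scores >= 0) and np.all(res.scores <= 1)
        assert np.all(res.positive_votes <= res.oob_counts)

    def test_vote_conservation_per_round(self, small_pu_dataset):
        # summed OOB counts = sum over rounds of (|U| - #unique in-bag);
        # reproduce the bootstrap draws from the same derived seed
        clf = RecordingClassifier()
        cfg = pc.BaggingConfig(n_bootstraps=10, classifier=clf, seed=5)
        res = pc.pu_bagging_scores(small_pu_dataset, cfg)
        rng = np.random.default_rng(pc.derive_seed(5, "bagging"))
        n_u = small_pu_dataset.u_indices.size
        n_kp = small_pu_dataset.n_kp
        expected_total = 0
        for _ in range(10):
            bag = rng.integers(0, n_u, size=n_kp)
            expected_total += n_u - np.unique(bag).size
        assert res.oob_counts.sum() == expected_total
        assert res.positive_votes.sum() <= res.oob_counts.sum()

    def test_training_set_size_is_kp_plus_matched_bag(self, small_pu_dataset):
        clf = RecordingClassifier()
        pc.pu_bagging_scores(small_pu_dataset, pc.BaggingConfig(n_bootstraps=5, classifier=clf, seed=0))
        n_kp = small_pu_dataset.n_kp
        assert all(train_n == 2 * n_kp for train_n, _ in clf.calls)

    def test_reproducibility(self, small_pu_dataset):
        cfg = pc.BaggingConfig(n_bootstraps=20, seed=9)
        a = pc.pu_bagging_scores(small_pu_dataset, cfg)
        b = pc.pu_bagging_scores(small_pu_dataset, cfg)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.oob_counts, b.oob_counts)

    def test_permutation_equivariance(self, small_pu_dataset):
        # permuting sample order permutes scores identically
        ds = small_pu_dataset
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        permuted = pc.PUDataset(
            features=ds.features[perm],
            pu_labels=ds.pu_labels[perm],
            truth_labels=ds.truth_labels[perm],
        )
        cfg = pc.BaggingConfig(n_bootstraps=15, seed=2)
        a = pc.pu_bagging_scores(ds, cfg)
        b = pc.pu_bagging_scores(permuted, cfg)
        # same multiset of (dataset index -> score) after mapping through perm
        score_a = dict(zip(ds.u_indices.tolist(), a.scores))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        score_b = {int(perm[j]): s for j, s in zip(b.u_indices, b.scores)}
        assert set(score_a) == set(score_b)
        # scores need not match sample-for-sample (bootstrap draws differ),
        # but the score multisets must coincide in distribution; check the
        # strong invariant on a deterministic classifier instead (scaling
        # off so the mock sees raw features)
        clf = RecordingClassifier()
        cfg = pc.BaggingConfig(n_bootstraps=60, classifier=clf, scale_on_bag=False, seed=2)
        a = pc.pu_bagging_scores(ds, cfg)
        # first-feature-sign classifier scores depend only on the sample itself
        for j, u in enumerate(ds.u_indices):
            if a.oob_counts[j] > 0:
                assert a.scores[j] == float(ds.features[u, 0] > 0)

    def test_separable_geometry_ranks_hidden_tp_above_tn(self, toy_pu_dataset):
        res = pc.pu_bagging_scores(toy_pu_dataset, pc.BaggingConfig(n_bootstraps=100, seed=1))
        truth_u = toy_pu_dataset.truth_labels[toy_pu_dataset.u_indices]
        tp_scores = res.scores[truth_u == 1]
        tn_scores = res.scores[truth_u == 0]
        assert tp_scores.min() > tn_scores.max()

    def test_never_oob_sample_gets_neutral_score(self):
        # one KP, one U sample: the bag always draws the single U sample,
        # so it is never OOB and must get score 0.5 with a warning
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        ds = pc.PUDataset(features=X, pu_labels=np.array([1, 0]))
        with pytest.warns(RuntimeWarning, match="never out-of-bag"):
            res = pc.pu_bagging_scores(ds, pc.BaggingConfig(n_bootstraps=3, seed=0))
        assert res.scores[0] == 0.5
        assert res.oob_counts[0] == 0

    def test_empty_kp_or_u_raises(self):
        X = np.random.default_rng(0).standard_normal((4, 2))
        all_p = pc.PUDataset(features=X, pu_labels=np.ones(4))
        all_u = pc.PUDataset(features=X, pu_labels=np.zeros(4))
        with pytest.raises(ValueError):
            pc.pu_bagging_scores(all_p, pc.BaggingConfig(n_bootstraps=2))
        with pytest.raises(ValueError):
            pc.pu_bagging_scores(all_u, pc.BaggingConfig(n_bootstraps=2))

    def test_scaling_uses_in_bag_statistics_only(self, small_pu_dataset):
        # a classifier that asserts its training data is standardized
        def asserting_clf(train_X, train_y, test_X, random_state=0):
            assert np.allclose(train_X.mean(axis=0), 0, atol=1e-9)
            sd = train_X.std(axis=0)
            assert np.allclose(sd[sd > 0], 1, atol=1e-9)
            return np.zeros(test_X.shape[0], dtype=np.int8)

        pc.pu_bagging_scores(
            small_pu_dataset,
            pc.BaggingConfig(n_bootstraps=4, classifier=asserting_clf, seed=1),
        )
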