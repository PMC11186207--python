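"""Shared fixtures: small synthetic datasets and a cheap mock classifier."""

import numpy as np
import pytest

import puconfide as pc


def nearest_centroid_classifier(train_X, train_y, test_X, random_state=0):
    """Deterministic, fast stand-in for the SVC contract in structural tests.

    Predicts the class of the nearer training-class centroid; raises on
    single-class input like the real contract.
    """
    if np.unique(train_y).size < 2:
        raise pc.SingleClassError("training labels contain a single class")
    c1 = train_X[train_y == 1].mean(axis=0)
    c0 = train_X[train_y == 0].mean(axis=0)
    d1 = np.linalg.norm(test_X - c1, axis=1)
    d0 = np.linalg.norm(test_X - c0, axis=1)
    return (d1 < d0).astype(np.int8)


@pytest.fixture
def centroid_clf():
    return nearest_centroid_classifier


@pytest.fixture
def toy_pu_dataset():
    """2-D separable PU dataset: KP cluster at (+5,+5), hidden TN at (-5,-5),
    hidden TP at (+5,+5) inside U."""
    rng = np.random.default_rng(42)
    kp = rng.normal(5.0, 0.3, size=(10, 2))
    hidden_tp = rng.normal(5.0, 0.3, size=(8, 2))
    hidden_tn = rng.normal(-5.0, 0.3, size=(12, 2))
    X = np.vstack([kp, hidden_tp, hidden_tn])
    pu = np.r_[np.ones(10), np.zeros(20)]
    truth = np.r_[np.ones(18), np.zeros(12)]
    return pc.PUDataset(features=X, pu_labels=pu, truth_labels=truth)


@pytest.fixture
def small_pu_dataset():
    """Well-separated synthetic PU dataset, small enough for fast runs."""
    cfg = pc.SyntheticConfig(
        n_samples=60, n_features=12, class_sep=2.0, tn_proportion=0.5, seed=11
    )
    return pc.make_pu_dataset(cfg, n_kp=15)
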