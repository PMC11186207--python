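"""Transductive PU bagging with out-of-bag vote aggregation.

Each bootstrap round draws ``|KP|`` unlabeled samples with replacement
and treats them as temporary negatives, fits a binary classifier on
(known positives = 1) vs (bagged unlabeled = 0), and predicts the class
of every unlabeled sample left out of the bag (out-of-bag, OOB).  Votes
are accumulated over rounds; the bagging score of an unlabeled sample is

    score = (# times predicted class 1 while OOB) / (# times OOB)

so scores live in [0, 1] and behave like a class-1 probability.  The
procedure is transductive: only the samples present at fit time are ever
scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from sklearn.svm import SVC, _libsvm

from .datasets import PUDataset
from .seeding import derive_seed

__all__ = [
    "BaggingConfig",
    "BaggingResult",
    "ClassifierContract",
    "svc_rbf_fit_predict",
    "fast_svc_rbf_fit_predict",
    "pu_bagging_scores",
]


# silence libsvm's optimizer chatter on the direct-call path (the public
# SVC API does the same inside fit())
_libsvm.set_verbosity_wrap(0)


class SingleClassError(ValueError):
    """Training labels contain a single class."""


class ClassifierContract(Protocol):
    """Pluggable classifier: fit on a two-class training set, predict test.

    Implementations must be deterministic given ``random_state`` and
    raise :class:`SingleClassError` when ``train_y`` is single-class.
    """

    def __call__(
        self,
        train_X: np.ndarray,
        train_y: np.ndarray,
        test_X: np.ndarray,
        random_state: int,
    ) -> np.ndarray: ...


def svc_rbf_fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    random_state: int = 0,
) -> np.ndarray:
    """Default classifier: RBF-kernel SVC with library-default hyperparameters.

    Hard class predictions (0/1) are returned; no tuning, no probability
    calibration.  Default hyperparameters are deliberate — with no ground
    truth available there is nothing trustworthy to tune against.
    """
    if np.unique(train_y).size < 2:
        raise SingleClassError("training labels contain a single class")
    clf = SVC(kernel="rbf", random_state=random_state)
    clf.fit(train_X, train_y)
    return clf.predict(test_X).astype(np.int8)


def fast_svc_rbf_fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    random_state: int = 0,
) -> np.ndarray:
    """RBF-SVC with default hyperparameters via direct libsvm calls.

    Mathematically identical to :func:`svc_rbf_fit_predict` (gamma =
    'scale', C = 1, tol = 1e-3) but skips scikit-learn's per-call input
    validation, which dominates runtime when thousands of tiny models
    are fitted per bagging run.  Exact prediction agreement with the
    public :class:`sklearn.svm.SVC` API is asserted in the test suite.
    """
    if np.unique(train_y).size < 2:
        raise SingleClassError("training labels contain a single class")
    X = np.ascontiguousarray(train_X, dtype=np.float64)
    y = np.ascontiguousarray(train_y, dtype=np.float64)
    T = np.ascontiguousarray(test_X, dtype=np.float64)
    x_var = X.var()
    gamma = 1.0 / (X.shape[1] * x_var) if x_var != 0 else 1.0  # SVC gamma='scale'
    fit_out = _libsvm.fit(
        X, y, svm_type=0, kernel="rbf", gamma=gamma, C=1.0, tol=1e-3,
        random_seed=int(random_state),
    )
    support, sv, n_class_sv, sv_coef, intercept = fit_out[:5]
    preds = _libsvm.predict(
        T, support, sv, n_class_sv, sv_coef, intercept,
        svm_type=0, kernel="rbf", gamma=gamma,
    )
    return preds.astype(np.int8)


@dataclass(frozen=True)
class BaggingConfig:
    """PU bagging parameters.

    ``n_bootstraps`` (T) defaults to 100 rounds.  ``scale_on_bag``
    standardizes features using mean/SD estimated from the in-bag
    training rows only, then applies the same transform to the OOB rows;
    constant features keep a unit divisor.
    """

    n_bootstraps: int = 100
    classifier: ClassifierContract = field(default=fast_svc_rbf_fit_predict)
    scale_on_bag: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")


@dataclass(frozen=True)
class BaggingResult:
    """Aggregated out-of-bag scores for the unlabeled set.

    ``u_indices`` maps positions of ``scores`` back into the dataset.
    ``scores[i] = positive_votes[i] / oob_counts[i]`` wherever
    ``oob_counts[i] > 0``; a sample never out-of-bag receives the neutral
    score 0.5 (and a warning is emitted).
    """

    u_indices: np.ndarray
    scores: np.ndarray
    oob_counts: np.ndarray
    positive_votes: np.ndarray

    def score_of(self, dataset_indices: np.ndarray) -> np.ndarray:
        """Scores for the given dataset indices (must all be U samples)."""
        pos = {int(u): i for i, u in enumerate(self.u_indices)}
        try:
            sel = [pos[int(i)] for i in np.atleast_1d(dataset_indices)]
        except KeyError as e:  # pragma: no cover - caller bug
            raise KeyError(f"index {e} is not an unlabeled sample") from e
        return self.scores[sel]


def _standardize(train_X: np.ndarray, test_X: np.ndarray):
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (train_X - mu) / sd, (test_X - mu) / sd


def pu_bagging_scores(data: PUDataset, config: BaggingConfig) -> BaggingResult:
    """Run T rounds of PU bagging and aggregate OOB votes into scores.

    Per round: draw ``|KP|`` unlabeled samples with replacement as
    temporary negatives, optionally standardize using in-bag statistics,
    fit the classifier on KP (class 1) + bag (class 0), and record a hard
    class prediction for every OOB unlabeled sample.
    """
    kp = data.kp_indices
    u = data.u_indices
    if kp.size < 1:
        raise ValueError("dataset has no known positives")
    if u.size < 1:
        raise ValueError("dataset has no unlabeled samples")

    X = data.features
    X_kp = X[kp]
    X_u = X[u]
    n_u = u.size
    rng = np.random.default_rng(derive_seed(config.seed, "bagging"))
    clf_rng = np.random.default_rng(derive_seed(config.seed, "clf"))
    clf_seeds = clf_rng.integers(0, 2**31, size=config.n_bootstraps)

    votes = np.zeros(n_u, dtype=np.int64)
    counts = np.zeros(n_u, dtype=np.int64)
    train_y = np.concatenate([np.ones(kp.size, dtype=np.int8), np.zeros(kp.size, dtype=np.int8)])

    for t in range(config.n_bootstraps):
        bag = rng.integers(0, n_u, size=kp.size)
        oob_mask = np.ones(n_u, dtype=bool)
        oob_mask[bag] = False
        oob = np.flatnonzero(oob_mask)
        if oob.size == 0:  # every U sample drawn in-bag; nothing to score
            continue
        train_X = np.concatenate([X_kp, X_u[bag]], axis=0)
        test_X = X_u[oob]
        if config.scale_on_bag:
            train_X, test_X = _standardize(train_X, test_X)
        preds = config.classifier(
            train_X, train_y, test_X, random_state=int(clf_seeds[t])
        )
        votes[oob] += preds
        counts[oob] += 1

    scores = np.full(n_u, 0.5, dtype=np.float64)
    seen = counts > 0
    scores[seen] = votes[seen] / counts[seen]
    if not np.all(seen):
        warnings.warn(
            f"{int(np.sum(~seen))} unlabeled sample(s) were never out-of-bag "
            f"after {config.n_bootstraps} rounds; assigned neutral score 0.5",
            RuntimeWarning,
            stacklevel=2,
        )
    return BaggingResult(u_indices=u, scores=scores, oob_counts=counts, positive_votes=votes)
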