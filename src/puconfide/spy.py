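"""K-fold spy-positive scoring of the known-positive set.

The known positives (KP) cannot be scored by a model trained on them,
so each repeat randomly partitions KP into K folds and, one fold at a
time, hides that fold inside the unlabeled set ("spy fold"), reruns PU
bagging with the remaining KP as positives, and records the bagging
scores the spies receive.  Pooling the K folds scores every KP sample
exactly once per repeat; R independent repeats quantify the variance of
the fold assignment.

Two summaries of a repeat's pooled spy scores are produced:

* EPR (explicit positive recall): fraction of spies whose score strictly
  exceeds a threshold (default 0.5).
* MBS (mean bagging score): the plain mean, requiring no decision
  boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .bagging import BaggingConfig, pu_bagging_scores
from .datasets import PUDataset
from .seeding import derive_rng, derive_seed

__all__ = ["SpyConfig", "SpyRunResult", "spy_fold_scores", "epr", "mbs"]


def epr(scores: np.ndarray, threshold: float = 0.5) -> float:
    """Explicit positive recall: fraction of scores strictly above ``threshold``.

    A score exactly equal to the threshold does not count as predicted
    positive.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("epr requires at least one score")
    return float(np.mean(s > threshold))


def mbs(scores: np.ndarray) -> float:
    """Mean bagging score: arithmetic mean of the pooled class-1 scores."""
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("mbs requires at least one score")
    return float(np.mean(s))


@dataclass(frozen=True)
class SpyConfig:
    """Spy-scoring parameters: K folds, R repeats, EPR threshold, bagging."""

    k_folds: int = 5
    n_repeats: int = 30
    epr_threshold: float = 0.5
    bagging: BaggingConfig = field(default_factory=BaggingConfig)
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 < self.epr_threshold < 1.0:
            raise ValueError("epr_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SpyRunResult:
    """Spy scores and per-repeat summaries.

    ``spy_scores`` has shape (R, |KP|); column j holds the scores of the
    KP sample at ``kp_indices[j]`` across repeats (each KP is a spy in
    exactly one fold per repeat).
    """

    kp_indices: np.ndarray
    spy_scores: np.ndarray
    epr_per_repeat: np.ndarray
    mbs_per_repeat: np.ndarray

    @property
    def n_repeats(self) -> int:
        return self.spy_scores.shape[0]


def _fold_partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k folds differing in size by <= 1."""
    perm = rng.permutation(n)
    return np.array_split(perm, k)


def spy_fold_scores(data: PUDataset, config: SpyConfig) -> SpyRunResult:
    """Run R repeats of K-fold spy scoring on the known-positive set."""
    kp = data.kp_indices
    if kp.size < config.k_folds:
        raise ValueError(
            f"spy scoring needs at least K={config.k_folds} known positives, "
            f"got {kp.size}"
        )
    n_kp = kp.size
    spy_scores = np.empty((config.n_repeats, n_kp), dtype=np.float64)

    for r in range(config.n_repeats):
        rng = derive_rng(config.seed, "spy-folds", r)
        folds = _fold_partition(n_kp, config.k_folds, rng)
        for f, fold in enumerate(folds):
            spy_dataset_idx = kp[fold]
            pu = data.pu_labels.copy()
            pu[spy_dataset_idx] = 0  # hide the spy fold inside U
            hidden = data.with_pu_labels(pu)
            bag_cfg = dataclasses.replace(
                config.bagging, seed=derive_seed(config.seed, "spy-bag", r, f)
            )
            result = pu_bagging_scores(hidden, bag_cfg)
            spy_scores[r, fold] = result.score_of(spy_dataset_idx)

    epr_per_repeat = np.array(
        [epr(spy_scores[r], config.epr_threshold) for r in range(config.n_repeats)]
    )
    mbs_per_repeat = np.array([mbs(spy_scores[r]) for r in range(config.n_repeats)])
    return SpyRunResult(
        kp_indices=kp,
        spy_scores=spy_scores,
        epr_per_repeat=epr_per_repeat,
        mbs_per_repeat=mbs_per_repeat,
    )
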