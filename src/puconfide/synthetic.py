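"""Synthetic two-class datasets with controlled separation and imbalance.

The generator emulates high-dimensional (p >= n) profiling data: a
fraction of "informative" features is drawn from Gaussian clusters placed
on class-specific hypercube vertices whose distance is set by
``class_sep`` (d = 0 makes both classes draws from the same
distribution), and a fraction of "redundant" features is built as random
linear combinations of the informative block, introducing covariance.
Any remainder is independent noise.  The construction is the standard
hypercube scheme of :func:`sklearn.datasets.make_classification`.

:func:`relabel_pu` converts a fully labeled dataset into a
positive-unlabeled scenario by revealing only ``n_kp`` randomly chosen
true positives as known positives.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.datasets import make_classification

from .datasets import LabeledDataset, PUDataset
from .seeding import derive_rng

__all__ = ["SyntheticConfig", "generate_synthetic", "relabel_pu", "make_pu_dataset"]


class ConfigurationError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic two-class generator.

    Attributes
    ----------
    n_samples, n_features : int
        Dataset shape; defaults give the wide p >= n regime (200 x 200).
    frac_informative : float
        Fraction of features carrying class signal (default 0.30).
    frac_redundant : float
        Fraction of features that are random linear combinations of the
        informative block (default 0.70).  ``frac_informative +
        frac_redundant`` may be < 1; the remainder is independent noise.
    class_sep : float
        Hypercube vertex distance d between the class centroids; 0 means
        the classes share one distribution (negative control), 2 is a
        well-separated problem.
    tn_proportion : float
        Proportion of true negatives among all samples (0 < x < 1).
    seed : int
        Master seed for the generator.
    """

    n_samples: int = 200
    n_features: int = 200
    frac_informative: float = 0.30
    frac_redundant: float = 0.70
    class_sep: float = 2.0
    tn_proportion: float = 0.50
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features must be >= 1")
        for name in ("frac_informative", "frac_redundant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_informative + self.frac_redundant > 1.0 + 1e-12:
            raise ConfigurationError("frac_informative + frac_redundant must be <= 1")
        if self.class_sep < 0:
            raise ConfigurationError("class_sep must be nonnegative")
        if not 0.0 < self.tn_proportion < 1.0:
            raise ConfigurationError("tn_proportion must be in (0, 1)")
        if self.n_informative < 1:
            raise ConfigurationError(
                "frac_informative * n_features rounds to zero informative features"
            )
        if self.n_true_negative < 1 or self.n_true_positive < 1:
            raise ConfigurationError("both classes must be non-empty")

    @property
    def n_informative(self) -> int:
        return int(round(self.frac_informative * self.n_features))

    @property
    def n_redundant(self) -> int:
        n_red = int(round(self.frac_redundant * self.n_features))
        return min(n_red, self.n_features - self.n_informative)

    @property
    def n_true_negative(self) -> int:
        # round to nearest; the remainder of the split goes to TP
        return int(round(self.tn_proportion * self.n_samples))

    @property
    def n_true_positive(self) -> int:
        return self.n_samples - self.n_true_negative

    def to_dict(self) -> dict:
        return asdict(self)


def generate_synthetic(config: SyntheticConfig) -> LabeledDataset:
    """Generate a labeled two-class dataset from ``config``.

    Class 1 is the true-positive (TP) class, class 0 the true-negative
    (TN) class; counts follow ``tn_proportion`` exactly.  Identical
    configs (including seed) produce bit-identical datasets.
    """
    n_tn = config.n_true_negative
    n = config.n_samples
    # weight chosen so floor(w*n) = n_tn - 1 exactly and the +1 remainder
    # lands on class 0, making the class counts deterministic
    w0 = (n_tn - 0.5) / n
    X, y = make_classification(
        n_samples=n,
        n_features=config.n_features,
        n_informative=config.n_informative,
        n_redundant=config.n_redundant,
        n_repeated=0,
        n_classes=2,
        n_clusters_per_class=1,
        weights=[w0],
        flip_y=0.0,
        # the toolkit requires strictly positive separation; d = 0 (both
        # classes one distribution) is realized by an infinitesimal value
        # 12 orders of magnitude below the unit cluster noise
        class_sep=max(float(config.class_sep), 1e-12),
        hypercube=True,
        shuffle=True,
        random_state=config.seed,
    )
    counts = np.bincount(y, minlength=2)
    if counts[0] != n_tn:  # pragma: no cover - guarded by the weight trick
        raise RuntimeError(f"class counts {counts} do not match requested TN={n_tn}")
    return LabeledDataset(features=X, truth_labels=y)


def relabel_pu(dataset: LabeledDataset, n_kp: int, seed: int) -> PUDataset:
    """Convert a labeled dataset to a PU scenario.

    Exactly ``n_kp`` samples drawn uniformly without replacement from the
    TP class become known positives; everything else is unlabeled.  The
    ground truth is retained on the result for evaluation-only use.
    """
    tp = dataset.tp_indices
    if n_kp <= 0:
        raise ValueError("n_kp must be positive")
    if n_kp > tp.size:
        raise ValueError(f"n_kp={n_kp} exceeds the {tp.size} true positives")
    rng = derive_rng(seed, "relabel")
    chosen = rng.choice(tp, size=n_kp, replace=False)
    pu = np.zeros(dataset.n_samples, dtype=np.int8)
    pu[chosen] = 1
    return PUDataset(
        features=dataset.features,
        pu_labels=pu,
        truth_labels=dataset.truth_labels,
    )


def make_pu_dataset(config: SyntheticConfig, n_kp: int, seed: int | None = None) -> PUDataset:
    """Generate synthetic data and relabel it as PU in one step.

    ``seed`` defaults to ``config.seed``; generation uses ``config.seed``
    and KP selection uses a child stream of ``seed`` so the two stages
    stay independent.
    """
    labeled = generate_synthetic(config)
    return relabel_pu(labeled, n_kp=n_kp, seed=config.seed if seed is None else seed)
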