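"""In-memory containers for labeled and positive-unlabeled (PU) data.

A :class:`LabeledDataset` carries the ground-truth two-class labels
(1 = true positive TP, 0 = true negative TN).  A :class:`PUDataset`
carries the labels visible to a PU learner (1 = known positive KP,
0 = unlabeled U) and, optionally, the hidden ground truth for
evaluation-only metrics such as the U-set ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "PUDataset"]


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"{name} must contain only 0/1 values, got {uniq}")
    return arr.astype(np.int8)


def _as_features(features) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D samples x features matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    return X


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with full ground-truth class labels.

    Parameters
    ----------
    features : (n_samples, n_features) float array
    truth_labels : (n_samples,) binary array, 1 = TP, 0 = TN
    """

    features: np.ndarray
    truth_labels: np.ndarray

    def __post_init__(self):
        X = _as_features(self.features)
        y = _as_binary(self.truth_labels, "truth_labels")
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and truth_labels disagree on n_samples")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "truth_labels", y)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def tp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.truth_labels == 1)

    @property
    def tn_indices(self) -> np.ndarray:
        return np.flatnonzero(self.truth_labels == 0)


@dataclass(frozen=True)
class PUDataset:
    """Feature matrix with positive/unlabeled labels.

    ``pu_labels`` is what models may see (1 = KP, 0 = U).  ``truth_labels``
    is optional hidden ground truth used only by evaluation metrics; no
    modeling operation reads it.
    """

    features: np.ndarray
    pu_labels: np.ndarray
    truth_labels: np.ndarray | None = None
    sample_ids: np.ndarray | None = field(default=None)
    #: set on datasets whose P labels were deliberately shuffled; relaxes
    #: the known-positive-is-true-positive invariant
    labels_permuted: bool = False

    def __post_init__(self):
        X = _as_features(self.features)
        pu = _as_binary(self.pu_labels, "pu_labels")
        if X.shape[0] != pu.shape[0]:
            raise ValueError("features and pu_labels disagree on n_samples")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "pu_labels", pu)
        if self.truth_labels is not None:
            truth = _as_binary(self.truth_labels, "truth_labels")
            if truth.shape[0] != X.shape[0]:
                raise ValueError("truth_labels disagree on n_samples")
            # every known positive must be a true positive
            if not self.labels_permuted and np.any(truth[pu == 1] == 0):
                raise ValueError("a known-positive sample has truth label TN")
            object.__setattr__(self, "truth_labels", truth)
        if self.sample_ids is not None:
            ids = np.asarray(self.sample_ids)
            if ids.shape[0] != X.shape[0]:
                raise ValueError("sample_ids disagree on n_samples")
            object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def kp_indices(self) -> np.ndarray:
        """Indices of known-positive samples, in dataset order."""
        return np.flatnonzero(self.pu_labels == 1)

    @property
    def u_indices(self) -> np.ndarray:
        """Indices of unlabeled samples, in dataset order."""
        return np.flatnonzero(self.pu_labels == 0)

    @property
    def n_kp(self) -> int:
        return int(np.sum(self.pu_labels == 1))

    def with_pu_labels(self, pu_labels: np.ndarray, labels_permuted: bool | None = None) -> "PUDataset":
        """Same features/truth, different P/U labeling."""
        return PUDataset(
            features=self.features,
            pu_labels=pu_labels,
            truth_labels=self.truth_labels,
            sample_ids=self.sample_ids,
            labels_permuted=self.labels_permuted if labels_permuted is None else labels_permuted,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: sample_id, f_0001.., pu_label[, truth_label]."""
        p = self.n_features
        width = max(4, len(str(p)))
        cols = [f"f_{i + 1:0{width}d}" for i in range(p)]
        df = pd.DataFrame(self.features, columns=cols)
        ids = (
            self.sample_ids
            if self.sample_ids is not None
            else np.array([f"s{i + 1:04d}" for i in range(self.n_samples)])
        )
        df.insert(0, "sample_id", ids)
        df["pu_label"] = self.pu_labels
        if self.truth_labels is not None:
            df["truth_label"] = self.truth_labels
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        pu_col: str = "pu_label",
        truth_col: str | None = "truth_label",
        id_col: str | None = "sample_id",
    ) -> "PUDataset":
        """Build from a feature table with a P/U column.

        All numeric columns other than the label/id columns are features.
        ``truth_col``/``id_col`` are used only if present.
        """
        if pu_col not in df.columns:
            raise KeyError(f"P/U label column {pu_col!r} not found")
        drop = [pu_col]
        truth = None
        if truth_col is not None and truth_col in df.columns:
            truth = df[truth_col].to_numpy()
            drop.append(truth_col)
        ids = None
        if id_col is not None and id_col in df.columns:
            ids = df[id_col].to_numpy()
            drop.append(id_col)
        feat = df.drop(columns=drop)
        non_numeric = [c for c in feat.columns if not pd.api.types.is_numeric_dtype(feat[c])]
        if non_numeric:
            raise ValueError(f"non-numeric feature columns: {non_numeric}")
        return cls(
            features=feat.to_numpy(dtype=np.float64),
            pu_labels=df[pu_col].to_numpy(),
            truth_labels=truth,
            sample_ids=ids,
        )
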