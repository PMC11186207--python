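"""Label-permutation null distribution for spy scores.

The null hypothesis is that the known-positive labels carry no
information: any equally sized subset of samples would score as well.
Each permutation reassigns the P labels to a uniformly random subset of
all samples (keeping the count), reruns the full K-fold spy-scoring
procedure on the permuted labeling, and records its EPR and MBS.  B
permutations yield the empirical null distributions against which the
actual-label scores are compared.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datasets import PUDataset
from .seeding import derive_rng, derive_seed
from .spy import SpyConfig, spy_fold_scores

__all__ = ["PermutationConfig", "NullDistribution", "permute_labels", "build_null"]


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-null parameters.

    ``n_permutations`` (B) is the number of label shuffles.  Each
    permutation runs ``n_repeats_per_permutation`` spy repeats (default
    1) and contributes the mean of their EPR/MBS as one null draw.
    """

    n_permutations: int = 30
    spy: SpyConfig = field(default_factory=SpyConfig)
    n_repeats_per_permutation: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 2:
            raise ValueError("n_permutations must be >= 2 (null SD uses n-1 dof)")
        if self.n_repeats_per_permutation < 1:
            raise ValueError("n_repeats_per_permutation must be >= 1")


@dataclass(frozen=True)
class NullDistribution:
    """EPR/MBS null draws across B label permutations, with audit trail."""

    epr_null: np.ndarray
    mbs_null: np.ndarray
    permutation_seeds: np.ndarray
    permuted_kp_indices: list[np.ndarray]

    @property
    def n_permutations(self) -> int:
        return self.epr_null.size


def permute_labels(data: PUDataset, seed: int) -> PUDataset:
    """Reassign the P labels to a uniformly random subset of all samples.

    Features and any ground-truth labels are untouched; only the P/U
    labeling moves, and the number of P labels is preserved.  P labels
    may land on any sample, including hidden true negatives — that is
    the point of the null.
    """
    rng = derive_rng(seed, "permute")
    chosen = rng.choice(data.n_samples, size=data.n_kp, replace=False)
    pu = np.zeros(data.n_samples, dtype=np.int8)
    pu[chosen] = 1
    return data.with_pu_labels(pu, labels_permuted=True)


def build_null(data: PUDataset, config: PermutationConfig) -> NullDistribution:
    """Build the permutation null of EPR and MBS.

    Each permutation's RNG is derived solely from the master seed and the
    permutation index, so draws are independent, reproducible, and
    invariant to execution order.
    """
    B = config.n_permutations
    epr_null = np.empty(B, dtype=np.float64)
    mbs_null = np.empty(B, dtype=np.float64)
    perm_seeds = np.empty(B, dtype=np.int64)
    permuted_sets: list[np.ndarray] = []

    for b in range(B):
        perm_seed = derive_seed(config.seed, "null-perm", b)
        perm_seeds[b] = perm_seed
        permuted = permute_labels(data, seed=perm_seed)
        permuted_sets.append(permuted.kp_indices.copy())
        spy_cfg = dataclasses.replace(
            config.spy,
            n_repeats=config.n_repeats_per_permutation,
            seed=derive_seed(config.seed, "null-spy", b),
        )
        try:
            run = spy_fold_scores(permuted, spy_cfg)
        except Exception as e:
            raise RuntimeError(
                f"spy scoring failed for permutation {b} (seed {perm_seed}): {e}"
            ) from e
        epr_null[b] = float(np.mean(run.epr_per_repeat))
        mbs_null[b] = float(np.mean(run.mbs_per_repeat))

    return NullDistribution(
        epr_null=epr_null,
        mbs_null=mbs_null,
        permutation_seeds=perm_seeds,
        permuted_kp_indices=permuted_sets,
    )
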