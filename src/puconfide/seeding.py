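"""Deterministic seed derivation.

A single master seed drives every stochastic step of the pipeline
(data generation, PU relabeling, bootstrap draws, fold splits, label
permutations).  Child seeds are derived from the master seed plus a
string/integer path through :class:`numpy.random.SeedSequence`, so
independent components get statistically independent streams and any
component can be rerun in isolation and reproduce its part exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]

# libsvm / scikit-learn accept seeds only up to 2**31 - 1
_SEED_MOD = 2**31


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(master_seed: int, *path: int | str) -> int:
    """Derive a child seed from ``master_seed`` and a path of keys.

    The same ``(master_seed, path)`` always yields the same child seed;
    distinct paths yield independent streams.
    """
    entropy = [int(master_seed)] + [_key_to_int(k) for k in path]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0]) % _SEED_MOD


def derive_rng(master_seed: int, *path: int | str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *path))
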