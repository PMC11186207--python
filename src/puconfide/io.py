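"""Reading and writing PU datasets as plain CSV/TSV tables.

The on-disk layout is one row per sample with columns
``sample_id, f_0001..f_p, pu_label[, truth_label]``.  Synthetic datasets
get a YAML sidecar (``<name>.yaml``) recording the generator
configuration and seeds for auditability.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .datasets import PUDataset
from .synthetic import SyntheticConfig

__all__ = ["write_dataset", "read_dataset"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def write_dataset(
    data: PUDataset,
    path: str | Path,
    config: SyntheticConfig | None = None,
    n_kp: int | None = None,
) -> Path:
    """Write a PU dataset to CSV/TSV; optionally record its provenance.

    When ``config`` is given, a ``<path stem>.yaml`` sidecar stores the
    full synthetic configuration so the dataset can be regenerated.
    """
    path = Path(path)
    df = data.to_frame()
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6g")
    if config is not None:
        sidecar = path.with_suffix(".yaml")
        meta = {"synthetic_config": config.to_dict()}
        if n_kp is not None:
            meta["n_kp"] = int(n_kp)
        sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return path


def read_dataset(
    path: str | Path,
    pu_col: str = "pu_label",
    truth_col: str | None = "truth_label",
    id_col: str | None = "sample_id",
) -> PUDataset:
    """Read a PU dataset from a CSV/TSV feature table."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return PUDataset.from_frame(df, pu_col=pu_col, truth_col=truth_col, id_col=id_col)
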