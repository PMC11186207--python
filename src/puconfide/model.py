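"""Model/Results interface for PU-learning confidence assessment.

:class:`PUConfidenceModel` is built from a feature table with P/U labels
(and optional hidden ground truth); :meth:`PUConfidenceModel.fit` runs
the full pipeline — K-fold spy scoring under the actual labels, a
label-permutation null, and the comparison statistics — and returns a
:class:`PUConfidenceResults` carrying the estimates, their null
reference, diagnostics, and a ``summary()`` table, in the spirit of
statsmodels model objects.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bagging import BaggingConfig, BaggingResult, pu_bagging_scores
from .datasets import PUDataset
from .permutation import NullDistribution, PermutationConfig, build_null
from .seeding import derive_seed
from .spy import SpyConfig, SpyRunResult, spy_fold_scores
from .stats import ConfidenceReport, compare_to_null, u_auc
from .synthetic import SyntheticConfig, make_pu_dataset

__all__ = ["PUConfidenceModel", "PUConfidenceResults"]


class PUConfidenceModel:
    """Permutation-testing confidence model for transductive PU learning.

    Parameters
    ----------
    data : PUDataset
        Features plus P/U labels; optional hidden ground truth enables
        the U-AUC diagnostic.
    spy_config, permutation_config, bagging_config : optional
        Pipeline parameters; defaults follow the method's standard
        operating point (K=5 folds, R=30 repeats, B=30 permutations,
        T=100 bootstraps, RBF-SVC with library defaults).
    """

    def __init__(
        self,
        data: PUDataset,
        spy_config: SpyConfig | None = None,
        permutation_config: PermutationConfig | None = None,
        bagging_config: BaggingConfig | None = None,
    ):
        self.data = data
        bag = bagging_config if bagging_config is not None else BaggingConfig()
        spy = spy_config if spy_config is not None else SpyConfig()
        spy = dataclasses.replace(spy, bagging=bag)
        perm = permutation_config if permutation_config is not None else PermutationConfig()
        perm = dataclasses.replace(perm, spy=spy)
        self.spy_config = spy
        self.permutation_config = perm
        self.bagging_config = bag

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        pu_col: str = "pu_label",
        truth_col: str | None = "truth_label",
        id_col: str | None = "sample_id",
        **configs,
    ) -> "PUConfidenceModel":
        """Build from a samples x features table with a P/U label column."""
        data = PUDataset.from_frame(df, pu_col=pu_col, truth_col=truth_col, id_col=id_col)
        return cls(data, **configs)

    @classmethod
    def from_synthetic(
        cls,
        config: SyntheticConfig,
        n_kp: int,
        **configs,
    ) -> "PUConfidenceModel":
        """Build from the synthetic generator (ground truth retained)."""
        return cls(make_pu_dataset(config, n_kp=n_kp), **configs)

    def fit(self, seed: int = 0, compute_u_auc: bool = True) -> "PUConfidenceResults":
        """Run spy scoring, the permutation null, and the statistics.

        ``seed`` is the master seed; every stochastic stage derives its
        own child stream from it, so refitting with the same seed
        reproduces the results exactly.
        """
        spy_cfg = dataclasses.replace(self.spy_config, seed=derive_seed(seed, "actual-spy"))
        spy_result = spy_fold_scores(self.data, spy_cfg)

        perm_cfg = dataclasses.replace(
            self.permutation_config,
            spy=self.spy_config,
            seed=derive_seed(seed, "null"),
        )
        null = build_null(self.data, perm_cfg)

        bagging_result = None
        u_auc_value = None
        if compute_u_auc and self.data.truth_labels is not None:
            bag_cfg = dataclasses.replace(
                self.bagging_config, seed=derive_seed(seed, "full-kp-bag")
            )
            bagging_result = pu_bagging_scores(self.data, bag_cfg)
            truth_u = self.data.truth_labels[self.data.u_indices]
            if np.unique(truth_u).size == 2:
                u_auc_value = u_auc(bagging_result, self.data.truth_labels)

        reports = {
            "EPR": compare_to_null(
                "EPR", spy_result.epr_per_repeat, null.epr_null, u_auc_value
            ),
            "MBS": compare_to_null(
                "MBS", spy_result.mbs_per_repeat, null.mbs_null, u_auc_value
            ),
        }
        return PUConfidenceResults(
            model=self,
            seed=seed,
            spy_result=spy_result,
            null=null,
            reports=reports,
            bagging_result=bagging_result,
            u_auc=u_auc_value,
        )


@dataclass
class PUConfidenceResults:
    """Fitted results: spy scores, permutation null, and statistics.

    ``reports`` maps metric name ("EPR", "MBS") to its
    :class:`ConfidenceReport`; ``u_auc`` and ``bagging_result`` are
    present only when ground truth was available.
    """

    model: PUConfidenceModel
    seed: int
    spy_result: SpyRunResult
    null: NullDistribution
    reports: dict[str, ConfidenceReport]
    bagging_result: BaggingResult | None = None
    u_auc: float | None = None

    def summary(self) -> str:
        """Human-readable summary table of both metrics."""
        lines = []
        lines.append("PU-learning confidence assessment (permutation test)")
        lines.append("=" * 68)
        d = self.model.data
        lines.append(
            f"samples: {d.n_samples}   features: {d.n_features}   "
            f"known positives: {d.n_kp}   unlabeled: {d.n_samples - d.n_kp}"
        )
        cfg = self.model.spy_config
        lines.append(
            f"spy folds K={cfg.k_folds}   repeats R={cfg.n_repeats}   "
            f"permutations B={self.model.permutation_config.n_permutations}   "
            f"bootstraps T={self.model.bagging_config.n_bootstraps}   seed={self.seed}"
        )
        if self.u_auc is not None:
            lines.append(f"U-AUC (vs hidden ground truth): {self.u_auc:.3f}")
        lines.append("-" * 68)
        hdr = f"{'metric':<7}{'mu':>8}{'mu0':>8}{'sigma':>8}{'z':>8}{'p':>11}{'delta':>8}{'95% CI':>17}  magnitude"
        lines.append(hdr)
        for name, r in self.reports.items():
            lines.append(
                f"{name:<7}{r.mu:>8.3f}{r.mu0:>8.3f}{r.sigma:>8.3f}{r.z:>8.2f}"
                f"{r.p_value:>11.2e}{r.cliffs_delta:>8.3f}"
                f"  [{r.delta_ci_low:>6.3f},{r.delta_ci_high:>6.3f}]  {r.magnitude}"
            )
        lines.append("-" * 68)
        return "\n".join(lines)

    # ---- tabular views ---------------------------------------------------

    def spy_scores_frame(self) -> pd.DataFrame:
        """Long-format spy scores: repeat, sample_id, spy_score."""
        sr = self.spy_result
        ids = (
            self.model.data.sample_ids[sr.kp_indices]
            if self.model.data.sample_ids is not None
            else sr.kp_indices
        )
        rows = []
        for r in range(sr.n_repeats):
            for j, sid in enumerate(ids):
                rows.append((r, sid, sr.spy_scores[r, j]))
        return pd.DataFrame(rows, columns=["repeat", "sample_id", "spy_score"])

    def spy_summary_frame(self) -> pd.DataFrame:
        """Per-repeat EPR and MBS."""
        sr = self.spy_result
        return pd.DataFrame(
            {
                "repeat": np.arange(sr.n_repeats),
                "epr": sr.epr_per_repeat,
                "mbs": sr.mbs_per_repeat,
            }
        )

    def null_frame(self) -> pd.DataFrame:
        """Per-permutation null EPR and MBS."""
        return pd.DataFrame(
            {
                "perm_index": np.arange(self.null.n_permutations),
                "epr": self.null.epr_null,
                "mbs": self.null.mbs_null,
            }
        )

    def u_scores_frame(self) -> pd.DataFrame | None:
        """Full-KP bagging scores of the U set (None without ground truth)."""
        if self.bagging_result is None:
            return None
        br = self.bagging_result
        ids = (
            self.model.data.sample_ids[br.u_indices]
            if self.model.data.sample_ids is not None
            else br.u_indices
        )
        df = pd.DataFrame(
            {"sample_id": ids, "score": br.scores, "oob_count": br.oob_counts}
        )
        if self.model.data.truth_labels is not None:
            df["truth_label"] = self.model.data.truth_labels[br.u_indices]
        return df

    def report_dict(self) -> dict:
        """JSON-ready report of both metrics plus run metadata."""
        return {
            "seed": self.seed,
            "n_samples": self.model.data.n_samples,
            "n_features": self.model.data.n_features,
            "n_known_positive": self.model.data.n_kp,
            "u_auc": self.u_auc,
            "metrics": {name: r.to_dict() for name, r in self.reports.items()},
        }

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts (CSV intermediates, JSON report, manifest)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        frames = {
            "spy_scores.csv": self.spy_scores_frame(),
            "spy_summary.csv": self.spy_summary_frame(),
            "null.csv": self.null_frame(),
        }
        uf = self.u_scores_frame()
        if uf is not None:
            frames["uauc_scores.csv"] = uf
        for name, df in frames.items():
            p = outdir / name
            df.to_csv(p, index=False, float_format="%.6f")
            paths[name] = p
        p = outdir / "report.json"
        p.write_text(json.dumps(self.report_dict(), indent=2))
        paths["report.json"] = p
        manifest = {
            "master_seed": int(self.seed),
            "spy_config": {
                "k_folds": self.model.spy_config.k_folds,
                "n_repeats": self.model.spy_config.n_repeats,
                "epr_threshold": self.model.spy_config.epr_threshold,
            },
            "permutation_config": {
                "n_permutations": self.model.permutation_config.n_permutations,
                "n_repeats_per_permutation": self.model.permutation_config.n_repeats_per_permutation,
            },
            "bagging_config": {
                "n_bootstraps": self.model.bagging_config.n_bootstraps,
                "scale_on_bag": self.model.bagging_config.scale_on_bag,
            },
            "permutation_seeds": [int(s) for s in self.null.permutation_seeds],
        }
        p = outdir / "manifest.yaml"
        p.write_text(yaml.safe_dump(manifest, sort_keys=False))
        paths["manifest.yaml"] = p
        return paths

    def plot_null_comparison(self, metric: str = "MBS", ax=None):
        """Histogram of the null draws with the actual-label mean marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        null = self.null.mbs_null if metric.upper() == "MBS" else self.null.epr_null
        actual = (
            self.spy_result.mbs_per_repeat
            if metric.upper() == "MBS"
            else self.spy_result.epr_per_repeat
        )
        ax.hist(null, bins=15, color="lightgray", edgecolor="gray", label="permuted labels")
        ax.axvline(float(np.mean(actual)), color="crimson", label="actual labels (mean)")
        ax.set_xlabel(metric.upper())
        ax.set_ylabel("permutations")
        ax.legend()
        return ax
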