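"""Comparison statistics: one-sample z-test, Cliff's Delta, U-set AUC.

The actual-label spy scores (R repeats) are compared to the permutation
null (B draws) two ways:

* an upper-tailed one-sample z-score, z = (mu - mu0) / sigma, where mu is
  the mean actual-label score, mu0 the null mean, and sigma the null SD
  with n-1 degrees of freedom; the p-value is the upper standard-normal
  tail; and
* Cliff's Delta, the nonparametric probability-of-superiority difference
  delta = (#(a_i > b_j) - #(a_i < b_j)) / (n_a * n_b), with a 95%
  confidence interval from Cliff's asymptotic consistent variance
  estimate and the conventional magnitude labels at |delta| thresholds
  0.147 / 0.33 / 0.474 (negligible / small / medium / large).

When ground truth is available for the unlabeled set, the U-AUC — the
ROC-AUC between U-set bagging scores and hidden labels — measures the
prediction performance the confidence statistics are meant to flag.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .bagging import BaggingResult

__all__ = [
    "DegenerateNullError",
    "z_test",
    "cliffs_delta",
    "delta_magnitude",
    "u_auc",
    "ConfidenceReport",
    "compare_to_null",
    "MAGNITUDE_THRESHOLDS",
]

#: |delta| boundaries for negligible / small / medium / large
MAGNITUDE_THRESHOLDS = (0.147, 0.33, 0.474)


class DegenerateNullError(ValueError):
    """The permutation null has zero spread; the z statistic is undefined."""


def z_test(actual_scores: np.ndarray, null_scores: np.ndarray) -> tuple[float, float]:
    """Upper-tailed one-sample z-test of the actual mean against the null.

    Returns ``(z, p)`` with ``z = (mean(actual) - mean(null)) / sd(null)``
    (sample SD, n-1 dof) and ``p`` the upper standard-normal tail.
    """
    a = np.asarray(actual_scores, dtype=np.float64)
    n = np.asarray(null_scores, dtype=np.float64)
    if a.size < 1:
        raise ValueError("actual_scores must be non-empty")
    if n.size < 2:
        raise ValueError("null_scores needs >= 2 draws for an SD with n-1 dof")
    sigma = float(np.std(n, ddof=1))
    if sigma == 0.0:
        raise DegenerateNullError(
            "permutation null is degenerate (zero standard deviation); "
            "the z statistic is undefined"
        )
    z = float((np.mean(a) - np.mean(n)) / sigma)
    p = float(sps.norm.sf(z))
    return z, p


def delta_magnitude(estimate: float) -> str:
    """Magnitude label for a Cliff's Delta estimate."""
    d = abs(estimate)
    lo, mid, hi = MAGNITUDE_THRESHOLDS
    if d < lo:
        return "negligible"
    if d < mid:
        return "small"
    if d < hi:
        return "medium"
    return "large"


def cliffs_delta(
    actual_scores: np.ndarray,
    null_scores: np.ndarray,
    confidence: float = 0.95,
) -> tuple[float, float, float, str]:
    """Cliff's Delta of ``actual`` over ``null`` with an asymptotic CI.

    Returns ``(estimate, ci_low, ci_high, magnitude)``.  The CI uses the
    consistent variance estimate of Cliff (1993) and the asymmetric
    transformation that keeps the interval inside [-1, 1]; a degenerate
    variance (complete dominance) collapses the interval onto the
    estimate.
    """
    a = np.asarray(actual_scores, dtype=np.float64)
    b = np.asarray(null_scores, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("cliffs_delta requires two non-empty samples")
    n1, n2 = a.size, b.size
    dom = np.sign(a[:, None] - b[None, :])
    d = float(dom.mean())

    row = dom.mean(axis=1)
    col = dom.mean(axis=0)
    if n1 > 1 and n2 > 1:
        s_sq = (
            n2**2 * np.sum((row - d) ** 2)
            + n1**2 * np.sum((col - d) ** 2)
            - np.sum((dom - d) ** 2)
        ) / (n1 * n2 * (n1 - 1) * (n2 - 1))
        s_sq = max(float(s_sq), 0.0)
    else:
        # minimal-sample fallback: entrywise variance over the pairs
        s_sq = float(np.var(dom, ddof=1) / (n1 * n2)) if n1 * n2 > 1 else 0.0
    z_crit = float(sps.norm.ppf(0.5 + confidence / 2.0))

    if s_sq == 0.0 or abs(d) == 1.0:
        lo = hi = d
    else:
        denom = 1.0 - d**2 + z_crit**2 * s_sq
        half = z_crit * np.sqrt(s_sq) * np.sqrt((1.0 - d**2) ** 2 + z_crit**2 * s_sq)
        lo = (d - d**3 - half) / denom
        hi = (d - d**3 + half) / denom
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    lo, hi = min(lo, d), max(hi, d)
    return d, lo, hi, delta_magnitude(d)


def u_auc(bagging: BaggingResult, truth_labels: np.ndarray) -> float:
    """ROC-AUC of the U-set bagging scores against hidden ground truth.

    ``truth_labels`` is the full-length truth vector; the U subset is
    selected through ``bagging.u_indices``.  Hidden true positives are
    class 1; ties contribute one half, per the rank-based definition.
    """
    truth = np.asarray(truth_labels)
    if truth.ndim != 1 or truth.size < bagging.u_indices.max() + 1:
        raise ValueError("truth_labels must cover every dataset index")
    y = truth[bagging.u_indices]
    if np.unique(y).size < 2:
        raise ValueError("U set contains a single ground-truth class; AUC undefined")
    return float(roc_auc_score(y, bagging.scores))


@dataclass(frozen=True)
class ConfidenceReport:
    """Comparison of actual-label scores against the permutation null.

    One report per scoring metric (EPR or MBS).  ``u_auc`` is filled only
    when ground truth for the unlabeled set was supplied.
    """

    metric: str
    mu: float
    mu0: float
    sigma: float
    z: float
    p_value: float
    cliffs_delta: float
    delta_ci_low: float
    delta_ci_high: float
    magnitude: str
    u_auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def compare_to_null(
    metric: str,
    actual_scores: np.ndarray,
    null_scores: np.ndarray,
    u_auc_value: float | None = None,
) -> ConfidenceReport:
    """Assemble the full confidence report for one scoring metric."""
    a = np.asarray(actual_scores, dtype=np.float64)
    n = np.asarray(null_scores, dtype=np.float64)
    z, p = z_test(a, n)
    d, lo, hi, mag = cliffs_delta(a, n)
    return ConfidenceReport(
        metric=metric,
        mu=float(np.mean(a)),
        mu0=float(np.mean(n)),
        sigma=float(np.std(n, ddof=1)),
        z=z,
        p_value=p,
        cliffs_delta=d,
        delta_ci_low=lo,
        delta_ci_high=hi,
        magnitude=mag,
        u_auc=u_auc_value,
    )
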