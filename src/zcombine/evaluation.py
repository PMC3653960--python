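"""Multiplicity control and method evaluation against simulation truth.

Provides Storey's fixed-lambda q-values, ROC curves averaged over replicate
datasets, rank statistics of the true DEGs, and the realized false discovery
proportion ("true FDR") at a target q-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

#: Number of points of the common FPR grid used to average ROC curves.
ROC_GRID_SIZE = 512

RANK_QUANTILE_NAMES = ("q1", "median", "mean", "q3", "max")


def storey_qvalue(p, lam: float = 0.5):
    """Storey (2002) q-values with a single fixed lambda.

    ``pi0`` is estimated as ``min(1, #{p > lam} / (m (1 - lam)))`` and the
    q-value of the i-th smallest p is the step-up envelope
    ``min_{j >= i} pi0 * m * p_(j) / j``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0 <= lam < 1:
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = min(1.0, (p > lam).sum() / (m * (1.0 - lam)))
    order = np.argsort(p, kind="stable")
    raw = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class EvalResult:
    """Averaged ROC curve plus per-dataset summaries."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc_per_dataset: np.ndarray = field(default=None)

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _as_bool(truth) -> np.ndarray:
    return np.asarray(truth, dtype=bool)


def roc_points(p_per_dataset, truth_per_dataset, grid_size: int = ROC_GRID_SIZE):
    """ROC curve of a p-value ranking, averaged pointwise over datasets.

    For each dataset the full empirical curve (thresholds = observed
    p-values) is computed, then interpolated onto a common FPR grid of
    ``grid_size`` points and averaged.  FPR = FP / #EEG, TPR = TP / #DEG.
    """
    if len(p_per_dataset) == 0:
        raise ValueError("need at least one dataset")
    grid = np.linspace(0.0, 1.0, grid_size)
    tprs, aucs = [], []
    for p, truth in zip(p_per_dataset, truth_per_dataset, strict=True):
        truth = _as_bool(truth)
        if truth.sum() == 0 or (~truth).sum() == 0:
            raise ValueError("truth must contain both DEGs and EEGs")
        # smaller p = stronger evidence, so score by -p
        fpr, tpr, _ = roc_curve(truth, -np.asarray(p, dtype=float))
        tprs.append(np.interp(grid, fpr, tpr))
        aucs.append(np.trapezoid(tpr, fpr))
    return EvalResult(
        fpr=grid,
        tpr=np.mean(tprs, axis=0),
        auc_per_dataset=np.asarray(aucs),
    )


def deg_rank_stats(p, truth, tie_rule: str = "average") -> dict[str, float]:
    """Quantiles of the ranks of true DEGs when genes are sorted by p-value.

    Ranks are 1-based over all genes with ``tie_rule`` handling of ties
    (default: average rank).  Low DEG ranks mean high detectability.
    Returns ``{"q1", "median", "mean", "q3", "max"}``.
    """
    truth = _as_bool(truth)
    if truth.sum() == 0:
        raise ValueError("truth contains no DEGs")
    ranks = stats.rankdata(np.asarray(p, dtype=float), method=tie_rule)[truth]
    q1, med, q3 = np.percentile(ranks, [25, 50, 75])
    return {
        "q1": float(q1),
        "median": float(med),
        "mean": float(ranks.mean()),
        "q3": float(q3),
        "max": float(ranks.max()),
    }


def aggregate_rank_stats(per_dataset: list[dict[str, float]]) -> pd.DataFrame:
    """Mean and SD of each rank quantile over replicate datasets."""
    frame = pd.DataFrame(per_dataset)[list(RANK_QUANTILE_NAMES)]
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})


def true_fdr_at_target(q, truth, target: float) -> float:
    """Realized false discovery proportion when rejecting genes with q <= target.

    Defined as 0 when nothing is rejected.
    """
    if not 0 < target < 1:
        raise ValueError("target FDR must lie in (0, 1)")
    truth = _as_bool(truth)
    reject = np.asarray(q, dtype=float) <= target
    n_reject = int(reject.sum())
    if n_reject == 0:
        return 0.0
    return float((reject & ~truth).sum() / n_reject)
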