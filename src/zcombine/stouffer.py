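"""Stouffer combined test with a data-driven null variance.

Per-compound z-scores of a gene are averaged into the Stouffer statistic

    T^S_g = (z_g1 + ... + z_gn) / sqrt(n),

which is normal with mean 0 under the gene's complex null even when the
partial tests are dependent (here: all compounds share one control arm).
Its null variance

    sigma^2 = (1/n) * sum_{i,j} Cov(z_i, z_j)
            = 1 + (2/n) * sum_{i<j} rho_ij          (unit marginals)

is unknown but estimable from the experiment itself: the z-score covariance
matrix is assumed common across equally expressed genes and is estimated by
the sample covariance of the z-score columns over a set of (putatively) null
genes.  The final test refers ``T^S_g / sigma_hat`` to the standard normal.

Procedure (steps S1-S5):

S1. z-scores of all partial tests        (:mod:`zcombine.partial_tests`)
S2. per-gene Stouffer statistics         (:func:`stouffer_statistic`)
S3. null-gene set {g : |T^S_g| <= x0}    (:func:`select_null_genes`)
S4. covariance and variance estimation   (:func:`estimate_covariance`,
                                          :func:`combined_variance`)
S5. two-sided standard-normal p-values   (:func:`stouffer_pvalues`)

A practical caveat: the sample covariance over genes selected by
``|T^S| <= x0`` conditions on the sum of the z-scores and therefore
*underestimates* the variance in the direction of the sum whenever x0 is
comparable to sigma (e.g. Var(T^S | |T^S| <= sigma) is about 0.16 sigma^2).
When the null proportion is high the selection step is unnecessary, and the
default pipeline uses all genes; then genes with real effects, if present,
inflate sigma_hat and the test errs on the conservative side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import EstimationError
from .evaluation import storey_qvalue
from .partial_tests import ExpressionExperiment, PartialTestTable, compute_partial_tests

logger = logging.getLogger("zcombine")


@dataclass
class DependenceModel:
    """Fitted null dependence structure of the per-compound z-scores."""

    x0: float                     # selection threshold on the T^S scale (inf = none)
    null_gene_ids: pd.Index       # genes used for covariance estimation
    sigma_hat: pd.DataFrame       # n x n sample covariance of z-scores
    rho_hat: pd.DataFrame         # corresponding correlations
    var_hat: float                # sigma^2 of the Stouffer statistic


@dataclass
class CombinedScores:
    """Per-gene combined statistic with p- and q-values for one method."""

    method: str                   # stouffer | tippett | fisher | dunnett
    statistic: pd.Series
    p_value: pd.Series
    q_value: pd.Series = None

    def with_qvalues(self, lam: float = 0.5) -> "CombinedScores":
        self.q_value = pd.Series(
            storey_qvalue(self.p_value.to_numpy(), lam=lam),
            index=self.p_value.index,
        )
        return self


def stouffer_statistic(z) -> float:
    """Stouffer/Liptak combination ``sum(z) / sqrt(len(z))`` of one gene."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("empty z-score vector")
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    return float(z.sum() / math.sqrt(z.size))


def stouffer_statistics(table: PartialTestTable) -> pd.Series:
    """Vectorized per-gene Stouffer statistics from a partial-test table (S2)."""
    z = table.z_score.to_numpy()
    return pd.Series(z.sum(axis=1) / math.sqrt(z.shape[1]), index=table.genes)


def select_null_genes(stouffer_stats: pd.Series, x0: float, min_size: int = 2):
    """Genes with ``|T^S_g| <= x0`` — the putative null set (S3).

    The threshold implements the "zero assumption": genes whose combined
    statistic sits near zero are taken to be surely equally expressed.
    Raises if fewer than ``min_size`` genes survive.
    """
    if not x0 > 0:
        raise ValueError("x0 must be positive")
    selected = stouffer_stats.index[np.abs(stouffer_stats.to_numpy()) <= x0]
    if len(selected) < min_size:
        raise EstimationError(
            f"only {len(selected)} genes with |T^S| <= {x0}; "
            f"need at least {min_size} — increase x0"
        )
    return selected


def estimate_covariance(z_null: pd.DataFrame):
    """Sample covariance/correlation of z-score columns over null genes (S4).

    Rows are the selected genes, columns the compounds.  Means are taken over
    the selected genes and the denominator is (count - 1).
    """
    if z_null.shape[0] < z_null.shape[1] + 1:
        raise EstimationError(
            f"need at least {z_null.shape[1] + 1} null genes, got {z_null.shape[0]}"
        )
    values = z_null.to_numpy(float)
    sigma = np.cov(values, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    diag = np.diag(sigma)
    if (diag == 0).any():
        bad = [c for c, v in zip(z_null.columns, diag) if v == 0]
        raise EstimationError(f"zero-variance z-score column(s): {bad}")
    denom = np.sqrt(np.outer(diag, diag))
    rho = sigma / denom
    cols = z_null.columns
    return (
        pd.DataFrame(sigma, index=cols, columns=cols),
        pd.DataFrame(rho, index=cols, columns=cols),
    )


def combined_variance(sigma_hat: pd.DataFrame, n: int) -> float:
    """Null variance of the Stouffer statistic: ``(1/n) * sum_ij Sigma_ij``.

    With unit diagonals this is ``1 + (2/n) * sum_{i<j} rho_ij``.  A
    non-positive result (possible with raw sample covariances and strong
    negative correlations) raises rather than being clipped.
    """
    sigma = np.asarray(sigma_hat, dtype=float)
    if sigma.shape != (n, n):
        raise ValueError(f"expected a {n}x{n} covariance matrix, got {sigma.shape}")
    if not np.allclose(sigma, sigma.T):
        raise ValueError("covariance matrix must be symmetric")
    var = float(sigma.sum() / n)
    if var <= 0:
        raise EstimationError(f"non-positive combined variance {var:.4g}")
    return var


def stouffer_pvalues(statistics: pd.Series, sigma: float) -> pd.Series:
    """Two-sided standard-normal p-values ``2 (1 - Phi(|T^S|/sigma))`` (S5)."""
    if not sigma > 0:
        raise EstimationError("sigma must be positive")
    values = np.asarray(statistics, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(values) / sigma)
    if isinstance(statistics, pd.Series):
        return pd.Series(p, index=statistics.index)
    return pd.Series(p)


def run_stouffer_pipeline(
    experiment: ExpressionExperiment,
    x0: float | None = None,
    x0_quantile: float | None = None,
    qvalue_lambda: float = 0.5,
) -> tuple[CombinedScores, DependenceModel]:
    """Run S1-S5 on an experiment; deterministic (no resampling anywhere).

    Parameters
    ----------
    x0 : float, optional
        Fixed null-selection threshold on the Stouffer-statistic scale.
    x0_quantile : float, optional
        Alternative rule: x0 = this quantile of |T^S| (adapts to the scale of
        the statistics).  Mutually exclusive with ``x0``.

    With neither given, every gene enters the covariance estimation (no
    selection).  This is the default: the selection step is superfluous when
    the null proportion is near one, and the plain sample covariance over a
    hard-thresholded set is truncation-biased (see module docstring).
    """
    if x0 is not None and x0_quantile is not None:
        raise ValueError("give at most one of x0 and x0_quantile")
    table = compute_partial_tests(experiment)                      # S1
    ts = stouffer_statistics(table)                                # S2
    n = experiment.n_compounds

    if x0_quantile is not None:
        if not 0 < x0_quantile < 1:
            raise ValueError("x0_quantile must lie in (0, 1)")
        x0 = float(np.quantile(np.abs(ts.to_numpy()), x0_quantile))
    if x0 is not None:
        null_ids = select_null_genes(ts, x0, min_size=n + 1)       # S3
        x0_used = float(x0)
    else:
        null_ids = ts.index
        x0_used = math.inf
    if len(null_ids) < len(ts):
        logger.warning(
            "stouffer: covariance from %d genes selected at |T^S| <= %.3g; "
            "hard selection truncates the statistic and can bias sigma^2 "
            "downward when x0 is small",
            len(null_ids), x0_used,
        )

    sigma_hat, rho_hat = estimate_covariance(table.z_score.loc[null_ids])  # S4
    var_hat = combined_variance(sigma_hat, n)
    if var_hat < 1.0:
        logger.warning(
            "stouffer: estimated sigma^2 = %.3f < 1 (negative correlations); kept",
            var_hat,
        )
    scores = CombinedScores(
        method="stouffer",
        statistic=ts,
        p_value=stouffer_pvalues(ts, math.sqrt(var_hat)),          # S5
    ).with_qvalues(lam=qvalue_lambda)
    model = DependenceModel(
        x0=x0_used,
        null_gene_ids=null_ids,
        sigma_hat=sigma_hat,
        rho_hat=rho_hat,
        var_hat=var_hat,
    )
    logger.info(
        "stouffer: |null set| = %d (x0 = %.3g), sigma^2 = %.3f, mean rho = %.3f",
        len(null_ids), x0_used, var_hat,
        float(rho_hat.to_numpy()[np.triu_indices(n, 1)].mean()) if n > 1 else 0.0,
    )
    return scores, model
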