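"""Comparator methods: permutation-calibrated Tippett and Fisher, and Dunnett.

Tippett's combination is the minimum partial p-value; Fisher's omnibus is
``-2 * sum(log p_i)``.  Both have known null laws only for *independent*
partial tests (min of uniforms, and chi-square with 2n degrees of freedom);
with a shared control arm the partial tests are dependent, so their null
distributions are approximated by whole-column label permutations: one
permutation of the sample-to-arm assignment is applied to every gene and the
full partial-test machinery is recomputed, preserving the dependence.

Dunnett's many-to-one test is the classical parametric comparator: the
statistic is ``max_i |t_i|`` with the variance pooled over all arms, and its
null is the equicorrelated (rho = 1/2 for equal arm sizes) multivariate t
with ``(n_arms)(k-1)`` degrees of freedom, evaluated by seeded Monte Carlo
on the common-denominator representation.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import stats

from ._exceptions import DesignError
from .partial_tests import CONTROL_ARM, ExpressionExperiment
from .stouffer import CombinedScores

logger = logging.getLogger("zcombine")

_PERM_CHUNK = 200
_EXHAUSTIVE_MAX_SAMPLES = 9
DUNNETT_DEFAULT_DRAWS = 100_000


@dataclass
class PermutationNull:
    """Permutation reference distribution of a combined statistic."""

    n_permutations: int
    scheme: str                   # "whole_column" or "exhaustive"
    per_gene_null: np.ndarray     # genes x B matrix of combined statistics
    seed: int | None


# ---------------------------------------------------------------------------
# combining functions
# ---------------------------------------------------------------------------

def tippett_statistic(p) -> float:
    """Minimum of the partial p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return float(p.min())


def fisher_statistic(p) -> float:
    """Fisher's omnibus statistic ``-2 * sum(log p_i)``.

    A zero p-value maps to +inf (flagged via a warning) so that orderings
    against permutation nulls remain well defined.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        logger.warning("fisher_statistic: zero p-value -> +inf sentinel")
    with np.errstate(divide="ignore"):
        return float(-2.0 * np.log(p).sum())


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def _arm_index(experiment: ExpressionExperiment) -> tuple[np.ndarray, np.ndarray]:
    """Arm index of each matrix column (0 = control) and per-arm sizes."""
    arms = [CONTROL_ARM] + experiment.compound_arms
    pos = {a: i for i, a in enumerate(arms)}
    idx = np.array([pos[a] for a in experiment.arm_of_sample.to_numpy()])
    sizes = np.bincount(idx, minlength=len(arms))
    return idx, sizes


def _partial_p_for_assignments(
    X: np.ndarray, X2: np.ndarray, labels: np.ndarray, sizes: np.ndarray
) -> np.ndarray:
    """Two-sided partial p-values for a batch of label assignments.

    ``labels`` is (batch, samples) of arm indices; returns an array of shape
    (genes, batch, n_compounds).  Uses the same pooled-t + central-t-CDF
    machinery as the observed statistics.
    """
    n_samples = labels.shape[1]
    batch = labels.shape[0]
    n_arms = sizes.size
    M = np.zeros((n_samples, batch * n_arms))
    rows = np.tile(np.arange(n_samples), batch)
    cols = np.repeat(np.arange(batch), n_samples) * n_arms + labels.ravel()
    M[rows, cols] = 1.0
    sums = (X @ M).reshape(-1, batch, n_arms)
    sumsq = (X2 @ M).reshape(-1, batch, n_arms)
    k = sizes.astype(float)
    means = sums / k
    ss = sumsq - sums ** 2 / k          # within-arm sums of squares
    k0 = k[0]
    p_out = np.empty((X.shape[0], batch, n_arms - 1))
    for i in range(1, n_arms):
        ki = k[i]
        dof = k0 + ki - 2.0
        sp2 = (ss[:, :, 0] + ss[:, :, i]) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (means[:, :, i] - means[:, :, 0]) / np.sqrt(sp2 * (1 / k0 + 1 / ki))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        p[np.isnan(t)] = 1.0            # zero variance and zero difference
        p_out[:, :, i - 1] = p
    return p_out


def _combined_from_partial_p(p: np.ndarray, combine: str) -> np.ndarray:
    if combine == "fisher":
        with np.errstate(divide="ignore"):
            return -2.0 * np.log(p).sum(axis=-1)
    if combine == "tippett":
        return p.min(axis=-1)
    raise ValueError(f"unknown combining function {combine!r}")


def _exhaustive_labelings(arm_idx: np.ndarray) -> np.ndarray:
    """All distinct arm-label assignments of the sample columns."""
    n = arm_idx.size
    if n > _EXHAUSTIVE_MAX_SAMPLES:
        raise ValueError(
            f"exhaustive enumeration supported up to {_EXHAUSTIVE_MAX_SAMPLES} "
            f"samples, got {n}"
        )
    distinct = sorted({tuple(perm) for perm in itertools.permutations(arm_idx)})
    return np.array(distinct)


def permutation_pvalues(
    experiment: ExpressionExperiment,
    combine: str = "fisher",
    n_permutations: int = 5000,
    seed: int = 0,
    pool_genes: bool = False,
    exhaustive: bool = False,
    alpha: float | None = None,
    return_null: bool = False,
):
    """Permutation-calibrated combined test (Tippett or Fisher).

    Sample-to-arm labels are permuted jointly across all samples as whole
    columns; the same permutation is applied to every gene and the partial
    tests plus the combined statistic are recomputed.  The per-gene p-value
    is the add-one estimator ``(1 + #more-extreme) / (B + 1)`` ("more
    extreme" = larger for Fisher, smaller for Tippett, ties included).

    With ``exhaustive=True`` all distinct labelings are enumerated (small
    designs only) and the p-value is the exact fraction ``#extreme / total``,
    the identity labeling counting itself.  ``pool_genes=True`` pools the
    permutation statistics of all genes into one reference distribution for
    finer p-value granularity.
    """
    if combine not in ("fisher", "tippett"):
        raise ValueError("combine must be 'fisher' or 'tippett'")
    scores_by_method, nulls = _permutation_scores(
        experiment,
        combines=(combine,),
        n_permutations=n_permutations,
        seed=seed,
        pool_genes=pool_genes,
        exhaustive=exhaustive,
        alpha=alpha,
    )
    if return_null:
        return scores_by_method[combine], nulls[combine]
    return scores_by_method[combine]


def _permutation_scores(
    experiment: ExpressionExperiment,
    combines: tuple[str, ...],
    n_permutations: int,
    seed: int,
    pool_genes: bool = False,
    exhaustive: bool = False,
    alpha: float | None = None,
):
    """Shared engine computing one permutation null for several combiners."""
    if n_permutations < 1 and not exhaustive:
        raise ValueError("need at least one permutation")
    X = experiment.expr.to_numpy(float)
    X2 = X ** 2
    arm_idx, sizes = _arm_index(experiment)
    genes = experiment.expr.index

    observed_p = _partial_p_for_assignments(X, X2, arm_idx[None, :], sizes)[:, 0, :]
    observed = {c: _combined_from_partial_p(observed_p, c) for c in combines}

    if exhaustive:
        labelings = _exhaustive_labelings(arm_idx)
        B = labelings.shape[0]
        batches = np.array_split(labelings, max(1, B // _PERM_CHUNK))
        scheme, used_seed = "exhaustive", None
    else:
        B = n_permutations
        rng = np.random.default_rng(seed)
        scheme, used_seed = "whole_column", seed
        if alpha is not None and 1.0 / (B + 1) > alpha:
            logger.warning(
                "permutation: B=%d gives minimum p-value %.2g > alpha=%.2g",
                B, 1.0 / (B + 1), alpha,
            )

    null = {c: np.empty((len(genes), B)) for c in combines}
    done = 0
    while done < B:
        if exhaustive:
            if not batches:
                break
            labels = batches.pop(0)
        else:
            size = min(_PERM_CHUNK, B - done)
            labels = np.stack([arm_idx[rng.permutation(arm_idx.size)]
                               for _ in range(size)])
        p = _partial_p_for_assignments(X, X2, labels, sizes)
        for c in combines:
            null[c][:, done:done + labels.shape[0]] = _combined_from_partial_p(p, c)
        done += labels.shape[0]

    out_scores, out_nulls = {}, {}
    for c in combines:
        obs = observed[c]
        stat_null = null[c]
        if c == "fisher":
            extreme = stat_null >= obs[:, None]
        else:
            extreme = stat_null <= obs[:, None]
        if pool_genes:
            flat = np.sort(stat_null.ravel())
            total = flat.size
            if c == "fisher":
                count = total - np.searchsorted(flat, obs, side="left")
            else:
                count = np.searchsorted(flat, obs, side="right")
            pvals = (1.0 + count) / (total + 1.0)
        elif exhaustive:
            pvals = extreme.sum(axis=1) / B
        else:
            pvals = (1.0 + extreme.sum(axis=1)) / (B + 1.0)
        out_scores[c] = CombinedScores(
            method=c,
            statistic=pd.Series(obs, index=genes),
            p_value=pd.Series(pvals, index=genes),
        ).with_qvalues()
        out_nulls[c] = PermutationNull(
            n_permutations=B, scheme=scheme, per_gene_null=stat_null, seed=used_seed
        )
    logger.info(
        "permutation: %s null with B=%d (%s) for %d genes",
        "+".join(combines), B, scheme, len(genes),
    )
    return out_scores, out_nulls


def permutation_pvalues_both(
    experiment: ExpressionExperiment,
    n_permutations: int = 5000,
    seed: int = 0,
    pool_genes: bool = False,
) -> dict[str, CombinedScores]:
    """Tippett and Fisher p-values from one shared permutation null."""
    scores, _ = _permutation_scores(
        experiment,
        combines=("fisher", "tippett"),
        n_permutations=n_permutations,
        seed=seed,
        pool_genes=pool_genes,
    )
    return scores


# ---------------------------------------------------------------------------
# Dunnett's many-to-one test
# ---------------------------------------------------------------------------

def dunnett_null_sample(
    n_compounds: int, dof: int, n_draws: int = DUNNETT_DEFAULT_DRAWS, seed: int = 0
) -> np.ndarray:
    """Sorted Monte Carlo sample of ``max_i |T_i|`` under the Dunnett null.

    Uses the common-denominator representation ``T_i = W_i / S`` with
    equicorrelated standard normals ``W_i = (Z_i - Z_0)/sqrt(2)`` (pairwise
    correlation 1/2, equal arm sizes) and ``S = sqrt(chi2_dof / dof)`` shared
    across compounds within a draw.
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_draws, n_compounds))
    Z0 = rng.standard_normal((n_draws, 1))
    W = (Z - Z0) / math.sqrt(2.0)
    denom = np.sqrt(rng.chisquare(dof, n_draws) / dof)
    return np.sort(np.abs(W).max(axis=1) / denom)


def dunnett_test(
    experiment: ExpressionExperiment,
    n_draws: int = DUNNETT_DEFAULT_DRAWS,
    seed: int = 0,
) -> CombinedScores:
    """Dunnett's test of every compound against the control, per gene.

    The statistic is ``max_i |t_i|`` with the error variance pooled over all
    arms (dof = n_arms * (k - 1)); the two-sided p-value is
    ``Pr(max_i |T_i| >= observed)`` under the equicorrelated multivariate t,
    estimated from one seeded Monte Carlo null sample shared by all genes.
    Requires equal replicate counts per arm.
    """
    k = experiment.replicates  # raises DesignError when unbalanced
    arms = [CONTROL_ARM] + experiment.compound_arms
    values = np.stack([experiment.arm_values(a) for a in arms])  # arms x genes x k
    means = values.mean(axis=2)
    ss = ((values - means[:, :, None]) ** 2).sum(axis=2)
    n_arms = len(arms)
    dof = n_arms * (k - 1)
    if dof <= 0:
        raise DesignError("need at least 2 replicates per arm")
    sp2 = ss.sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (means[1:] - means[0]) / np.sqrt(sp2 * 2.0 / k)
    t[np.isnan(t)] = 0.0
    max_abs_t = np.abs(t).max(axis=0)

    null = dunnett_null_sample(n_arms - 1, dof, n_draws=n_draws, seed=seed)
    count_ge = null.size - np.searchsorted(null, max_abs_t, side="left")
    pvals = (1.0 + count_ge) / (null.size + 1.0)
    logger.info(
        "dunnett: %d genes, %d compounds, dof=%d, MC null of %d draws",
        experiment.n_genes, n_arms - 1, dof, n_draws,
    )
    return CombinedScores(
        method="dunnett",
        statistic=pd.Series(max_abs_t, index=experiment.expr.index),
        p_value=pd.Series(pvals, index=experiment.expr.index),
    ).with_qvalues()
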