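"""Per-gene partial tests of each compound arm against a shared control.

A "partial test" is the two-sample comparison of one compound arm versus the
common control arm for a single gene.  Because a gene-level (complex) null
hypothesis is the intersection of the per-compound nulls, the per-compound
statistics are later combined; this module produces the building blocks:

* the pooled-variance two-sample t statistic ``T_gi`` for gene ``g`` and
  compound ``i``, with degrees of freedom ``k_control + k_compound - 2``;
* its two-sided p-value ``p_gi = 2 * (1 - F_dof(|T_gi|))``;
* the signed z-score ``z_gi = Phi^{-1}(F_dof(T_gi))``, the probability
  integral transform of the t statistic through the central t CDF.  Under a
  normal null the pooled t statistic is exactly t-distributed, so ``z_gi``
  is exactly standard normal.

The pooled (rather than Welch) t is used because the z transform requires a
known exact null CDF; positive t means compound mean above control mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import DesignError

logger = logging.getLogger("zcombine")

CONTROL_ARM = "control"

#: Largest |z| representable safely through double-precision normal quantiles;
#: non-finite or underflowing transforms are clipped here and flagged.
Z_CLIP = 8.2


@dataclass
class ExpressionExperiment:
    """A normalized expression matrix with a one-control, multi-compound design.

    Parameters
    ----------
    expr : pandas.DataFrame
        Genes x samples matrix of normalized (log-scale) expression values.
    arm_of_sample : pandas.Series
        Maps sample id -> arm name.  Exactly one arm must be named
        ``"control"``; every arm needs at least two samples.
    """

    expr: pd.DataFrame
    arm_of_sample: pd.Series

    def __post_init__(self) -> None:
        self.arm_of_sample = pd.Series(self.arm_of_sample)
        design_samples = list(self.arm_of_sample.index)
        matrix_samples = list(self.expr.columns)
        missing = [s for s in design_samples if s not in self.expr.columns]
        if missing:
            raise DesignError(
                f"design references samples absent from the matrix: {missing}"
            )
        extra = [s for s in matrix_samples if s not in self.arm_of_sample.index]
        if extra:
            raise DesignError(f"matrix samples missing from the design: {extra}")
        # canonical column order = design order
        self.expr = self.expr.loc[:, design_samples]
        if self.expr.index.duplicated().any():
            dupes = self.expr.index[self.expr.index.duplicated()].unique().tolist()
            raise DesignError(f"duplicated gene identifiers: {dupes[:5]}")
        arms = self.arm_of_sample.unique().tolist()
        if CONTROL_ARM not in arms:
            raise DesignError("no arm named 'control' in the design")
        counts = self.arm_of_sample.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise DesignError(
                f"arms with fewer than 2 replicates: {small.to_dict()}"
            )
        if len(arms) < 2:
            raise DesignError("need at least one compound arm besides the control")
        if self.expr.isna().any().any():
            raise DesignError("expression matrix contains missing values")

    # -- design accessors ---------------------------------------------------
    @property
    def compound_arms(self) -> list[str]:
        return [a for a in self.arm_of_sample.unique() if a != CONTROL_ARM]

    @property
    def n_compounds(self) -> int:
        return len(self.compound_arms)

    @property
    def arm_samples(self) -> dict[str, list]:
        return {
            arm: list(self.arm_of_sample.index[self.arm_of_sample == arm])
            for arm in self.arm_of_sample.unique()
        }

    @property
    def replicates(self) -> int:
        """Common replicate count per arm; raises if arms are unbalanced."""
        counts = set(self.arm_of_sample.value_counts())
        if len(counts) != 1:
            raise DesignError("arms have unequal replicate counts")
        return counts.pop()

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    def arm_values(self, arm: str) -> np.ndarray:
        return self.expr[self.arm_samples[arm]].to_numpy(float)


@dataclass
class PartialTestTable:
    """Per-gene, per-compound t statistics with p-values and z-scores."""

    t_stat: pd.DataFrame          # genes x compounds
    dof: pd.Series                # per compound
    p_two_sided: pd.DataFrame = field(default=None)
    z_score: pd.DataFrame = field(default=None)

    @property
    def genes(self) -> pd.Index:
        return self.t_stat.index

    @property
    def compounds(self) -> list[str]:
        return list(self.t_stat.columns)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Pooled-variance two-sample t of ``b`` (compound) versus ``a`` (control).

    Rows are genes, columns replicates.  Returns the t vector and the shared
    degrees of freedom.  Genes where both within-arm variances and the mean
    difference vanish get t = 0; a zero pooled variance with a nonzero
    difference maps to a signed infinity sentinel (flagged by the caller).
    """
    ka, kb = a.shape[1], b.shape[1]
    dof = ka + kb - 2
    diff = b.mean(axis=1) - a.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    sp2 = (ssa + ssb) / dof
    se = np.sqrt(sp2 * (1.0 / ka + 1.0 / kb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    if degenerate.any():
        zero_diff = degenerate & (diff == 0)
        t[zero_diff] = 0.0
        blown = degenerate & (diff != 0)
        t[blown] = np.sign(diff[blown]) * np.inf
        logger.warning(
            "partial_tests: %d gene(s) with zero pooled variance "
            "(%d set to t=0, %d to +/-inf sentinel)",
            int(degenerate.sum()), int(zero_diff.sum()), int(blown.sum()),
        )
    return t, float(dof)


def compute_partial_t(experiment: ExpressionExperiment) -> PartialTestTable:
    """Pooled two-sample t statistics of every compound arm versus control."""
    control = experiment.arm_values(CONTROL_ARM)
    cols = {}
    dof = {}
    for arm in experiment.compound_arms:
        t, d = _pooled_t(control, experiment.arm_values(arm))
        cols[arm] = t
        dof[arm] = d
    table = PartialTestTable(
        t_stat=pd.DataFrame(cols, index=experiment.expr.index),
        dof=pd.Series(dof),
    )
    return table


def z_transform(t, dof):
    """Signed probability-integral transform of a t statistic to a z-score.

    ``z = Phi^{-1}(F_dof(t))`` computed tail-wise so that extreme statistics
    keep full relative precision; exactly antisymmetric in ``t``.  Non-finite
    inputs and underflowing quantiles are clipped to ``+/- Z_CLIP``.
    """
    t = np.asarray(t, dtype=float)
    if np.ndim(dof) == 0 and float(dof) <= 0:
        raise ValueError("degrees of freedom must be positive")
    sf = stats.t.sf(np.abs(t), dof)
    with np.errstate(over="ignore"):
        z = np.sign(t) * stats.norm.isf(sf)
    nonfinite = ~np.isfinite(z)
    if nonfinite.any():
        logger.warning(
            "z_transform: %d score(s) clipped to |z| = %.1f",
            int(nonfinite.sum()), Z_CLIP,
        )
    z = np.clip(np.where(nonfinite, np.sign(t) * Z_CLIP, z), -Z_CLIP, Z_CLIP)
    return z if z.ndim else float(z)


def compute_partial_tests(experiment: ExpressionExperiment) -> PartialTestTable:
    """Full partial-test table: t statistics, p-values, and z-scores (step S1)."""
    table = compute_partial_t(experiment)
    t = table.t_stat.to_numpy()
    dof = table.dof.to_numpy()
    p = 2.0 * stats.t.sf(np.abs(t), dof[None, :])
    z = z_transform(t, dof[None, :])
    table.p_two_sided = pd.DataFrame(
        p, index=table.t_stat.index, columns=table.t_stat.columns
    )
    table.z_score = pd.DataFrame(
        z, index=table.t_stat.index, columns=table.t_stat.columns
    )
    logger.info(
        "partial_tests: %d genes x %d compounds, dof=%s",
        len(table.genes), len(table.compounds), dict(table.dof),
    )
    return table
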