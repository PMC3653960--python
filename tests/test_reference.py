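import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from zcombine import (
    DesignError,
    ExpressionExperiment,
    dunnett_test,
    fisher_statistic,
    permutation_pvalues,
    permutation_pvalues_both,
    tippett_statistic,
)
from zcombine.reference import dunnett_null_sample


# -- combining functions -----------------------------------------------------

def test_tippett_statistic_values():
    assert tippett_statistic([1, 1, 1]) == 1.0
    assert tippett_statistic([0.3, 0.05, 0.7]) == 0.05
    with pytest.raises(ValueError):
        tippett_statistic([])
    with pytest.raises(ValueError):
        tippett_statistic([1.2])


def test_fisher_statistic_values():
    assert fisher_statistic([1, 1, 1]) == 0.0
    assert fisher_statistic([0.05] * 3) == pytest.approx(-6 * math.log(0.05))
    assert np.isinf(fisher_statistic([0.0, 0.5]))


def test_min_p_order_statistic_law():
    """min of 3 independent uniforms has CDF 1-(1-x)^3."""
    rng = np.random.default_rng(0)
    mins = rng.uniform(size=(100_000, 3)).min(axis=1)
    ks = stats.kstest(mins, lambda x: 1 - (1 - x) ** 3)
    assert ks.pvalue > 0.01


def test_fisher_null_is_chi2_with_2n_dof():
    """For independent partial tests the omnibus statistic is chi2_6 (n=3)."""
    rng = np.random.default_rng(1)
    p = rng.uniform(size=(100_000, 3))
    statistic = -2 * np.log(p).sum(axis=1)
    assert stats.kstest(statistic, stats.chi2(6).cdf).pvalue > 0.01


# -- permutation calibration -------------------------------------------------

def _enumerated_oracle_p(experiment, combine):
    """Independent brute force: every distinct label assignment, partial
    p-values computed gene-by-gene through scipy, exact permutation p."""
    X = experiment.expr.to_numpy()
    labels = experiment.arm_of_sample.to_numpy()
    arms = ["control"] + experiment.compound_arms

    def combined(stat_labels):
        groups = {a: X[:, np.asarray(stat_labels) == a] for a in arms}
        out = np.empty(X.shape[0])
        for g in range(X.shape[0]):
            ps = []
            for a in arms[1:]:
                res = stats.ttest_ind(
                    groups[a][g], groups["control"][g], equal_var=True
                )
                ps.append(res.pvalue)
            out[g] = min(ps) if combine == "tippett" else -2 * np.log(ps).sum()
        return out

    observed = combined(labels)
    all_labelings = sorted({tuple(sig) for sig in itertools.permutations(labels)})
    null = np.stack([combined(list(sig)) for sig in all_labelings])
    if combine == "tippett":
        count = (null <= observed[None, :]).sum(axis=0)
    else:
        count = (null >= observed[None, :]).sum(axis=0)
    return count / len(all_labelings)


@pytest.mark.parametrize("combine", ["tippett", "fisher"])
def test_exhaustive_permutation_matches_enumeration(
    small_threearm_experiment, combine
):
    scores = permutation_pvalues(
        small_threearm_experiment, combine=combine, exhaustive=True
    )
    oracle = _enumerated_oracle_p(small_threearm_experiment, combine)
    np.testing.assert_allclose(scores.p_value.to_numpy(), oracle, atol=1e-12)


def test_permutation_p_within_arm_relabeling_invariant(small_threearm_experiment):
    base = permutation_pvalues(
        small_threearm_experiment, combine="fisher", exhaustive=True
    )
    cols = ["c2", "c1", "a2", "a1", "b1", "b2"]  # swap replicates within arms
    shuffled = ExpressionExperiment(
        small_threearm_experiment.expr[cols],
        small_threearm_experiment.arm_of_sample[cols],
    )
    other = permutation_pvalues(shuffled, combine="fisher", exhaustive=True)
    np.testing.assert_allclose(
        base.p_value.to_numpy(), other.p_value.to_numpy(), atol=1e-12
    )


def test_addone_estimator_bounds(small_threearm_experiment):
    scores, null = permutation_pvalues(
        small_threearm_experiment, combine="fisher", n_permutations=49,
        seed=2, return_null=True,
    )
    p = scores.p_value.to_numpy()
    assert (p >= 1 / 50).all() and (p <= 1.0).all()
    assert null.per_gene_null.shape == (3, 49)
    assert null.scheme == "whole_column"


def test_permutation_seed_determinism(small_threearm_experiment):
    a = permutation_pvalues(small_threearm_experiment, "fisher",
                            n_permutations=100, seed=5)
    b = permutation_pvalues(small_threearm_experiment, "fisher",
                            n_permutations=100, seed=5)
    pd.testing.assert_series_equal(a.p_value, b.p_value)


def test_pool_genes_gives_finer_granularity(small_threearm_experiment):
    pooled = permutation_pvalues(
        small_threearm_experiment, "fisher", n_permutations=100, seed=1,
        pool_genes=True,
    )
    assert pooled.p_value.min() >= 1 / (3 * 100 + 1)


def test_shared_engine_matches_single_method(small_threearm_experiment):
    both = permutation_pvalues_both(
        small_threearm_experiment, n_permutations=200, seed=9
    )
    single = permutation_pvalues(
        small_threearm_experiment, "tippett", n_permutations=200, seed=9
    )
    pd.testing.assert_series_equal(both["tippett"].p_value, single.p_value)


def test_tippett_bonferroni_bound(small_threearm_experiment):
    """P(min p <= x) <= n x: the exact permutation p cannot be smaller than
    the Bonferroni-corrected minimum partial p-value by more than enumeration
    granularity."""
    scores = permutation_pvalues(
        small_threearm_experiment, combine="tippett", exhaustive=True
    )
    min_p = scores.statistic.to_numpy()
    n = small_threearm_experiment.n_compounds
    granularity = 1.0 / 90  # distinct labelings of the 2+2+2 design
    assert (scores.p_value.to_numpy() <= np.minimum(1, n * min_p) + granularity).all()


# -- Dunnett -----------------------------------------------------------------

def _dunnett_two_sided_oracle(c, n, dof):
    """Numeric integration of P(max_i |T_i| > c) under the equicorrelated
    (rho = 1/2) multivariate t with common denominator."""

    def inner(z, u):
        s = math.sqrt(u / dof)
        width = stats.norm.cdf(z + math.sqrt(2) * c * s) - stats.norm.cdf(
            z - math.sqrt(2) * c * s
        )
        return width ** n * stats.norm.pdf(z) * stats.chi2(dof).pdf(u)

    prob, _ = integrate.dblquad(
        inner, 0, dof * 8, lambda u: -8, lambda u: 8, epsabs=1e-8
    )
    return 1.0 - prob


def test_dunnett_null_sample_matches_quadrature():
    null = dunnett_null_sample(n_compounds=3, dof=76, n_draws=200_000, seed=0)
    mc_p = (null >= 2.41).mean()
    assert mc_p == pytest.approx(_dunnett_two_sided_oracle(2.41, 3, 76), abs=0.005)


def test_dunnett_single_compound_is_two_sample_t():
    rng = np.random.default_rng(4)
    expr = pd.DataFrame(rng.normal(size=(5, 10)),
                        index=[f"g{i}" for i in range(5)],
                        columns=[f"s{i}" for i in range(10)])
    arms = pd.Series(["control"] * 5 + ["compound_1"] * 5, index=expr.columns)
    experiment = ExpressionExperiment(expr, arms)
    scores = dunnett_test(experiment, n_draws=400_000, seed=1)
    for g in range(5):
        t_res = stats.ttest_ind(
            expr.iloc[g, 5:], expr.iloc[g, :5], equal_var=True
        )
        assert scores.p_value.iloc[g] == pytest.approx(t_res.pvalue, abs=0.005)


def test_dunnett_matches_scipy_reference(small_threearm_experiment):
    """Cross-check against scipy's Dunnett implementation on one gene."""
    experiment = small_threearm_experiment
    scores = dunnett_test(experiment, n_draws=400_000, seed=2)
    X = experiment.expr
    for g in range(3):
        ref = stats.dunnett(
            X.iloc[g][["a1", "a2"]].to_numpy(),
            X.iloc[g][["b1", "b2"]].to_numpy(),
            control=X.iloc[g][["c1", "c2"]].to_numpy(),
            random_state=np.random.default_rng(0),
        )
        assert scores.p_value.iloc[g] == pytest.approx(min(ref.pvalue), abs=0.02)


def test_dunnett_bounds_and_degenerate_cases():
    rng = np.random.default_rng(6)
    expr = pd.DataFrame(rng.normal(size=(20, 12)),
                        index=[f"g{i}" for i in range(20)],
                        columns=[f"s{i}" for i in range(12)])
    arms = pd.Series(["control"] * 3 + ["compound_1"] * 3
                     + ["compound_2"] * 3 + ["compound_3"] * 3,
                     index=expr.columns)
    experiment = ExpressionExperiment(expr, arms)
    scores = dunnett_test(experiment, seed=0)
    dof = 4 * (3 - 1)
    max_t = scores.statistic.to_numpy()
    unadjusted = 2 * stats.t.sf(max_t, dof)
    assert (scores.p_value.to_numpy() >= unadjusted - 0.01).all()
    # p <= Bonferroni over the three comparisons (each with its own pairwise
    # dof = 4 would be smaller; the pooled dof makes the bound safely loose)
    bonferroni = np.minimum(1.0, 3 * unadjusted)
    assert (scores.p_value.to_numpy() <= bonferroni + 0.01).all()

    flat = ExpressionExperiment(
        expr * 0.0 + 1.0, arms
    )
    flat_scores = dunnett_test(flat, n_draws=1000, seed=0)
    assert (flat_scores.statistic == 0).all()
    assert (flat_scores.p_value == 1.0).all()


def test_dunnett_requires_equal_arm_sizes():
    rng = np.random.default_rng(7)
    expr = pd.DataFrame(rng.normal(size=(2, 7)), index=["g1", "g2"],
                        columns=[f"s{i}" for i in range(7)])
    arms = pd.Series(["control"] * 3 + ["compound_1"] * 2 + ["compound_2"] * 2,
                     index=expr.columns)
    with pytest.raises(DesignError, match="unequal"):
        dunnett_test(ExpressionExperiment(expr, arms))
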