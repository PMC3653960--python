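"""File formats, run configuration, and the full simulation benchmark.

All files are plain tab-separated text:

* expression TSV — header row of sample ids, first column ``gene_id``;
* design TSV — columns ``sample_id`` and ``arm`` (``control`` or any
  compound arm name);
* truth TSV — columns ``gene_id`` and ``is_deg`` (0/1);
* results TSV — ``gene_id, method, statistic, p_value, q_value`` plus
  ``is_null_set_member`` for the Stouffer method;
* report TSVs from the benchmark — ``rank_stats.tsv`` (DEG rank statistics),
  ``true_fdr.tsv`` (realized FDR at the target levels), ``roc.tsv``.

Input expression values are assumed to be already normalized (e.g. RMA for
microarrays); no preprocessing is applied here.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ConfigurationError, DesignError
from .evaluation import (
    aggregate_rank_stats,
    deg_rank_stats,
    roc_points,
    true_fdr_at_target,
)
from .partial_tests import CONTROL_ARM, ExpressionExperiment
from .reference import dunnett_test, permutation_pvalues_both
from .simulate import ERROR_FAMILIES, SimulationConfig, simulate_many
from .stouffer import CombinedScores, DependenceModel, run_stouffer_pipeline

logger = logging.getLogger("zcombine")

ALL_METHODS = ("stouffer", "tippett", "fisher", "dunnett")

# fixed offsets separating the seed streams of independent random stages
_PERM_SEED_OFFSET = 10_007
_DUNNETT_SEED_OFFSET = 20_011


@dataclass
class RunConfig:
    """Top-level configuration of a benchmark or analysis run."""

    method: str = "stouffer"
    x0: float | None = None
    x0_quantile: float | None = None
    permutations: int = 1000
    alpha: float = 0.05
    fdr_targets: tuple[float, ...] = (0.1, 0.2)
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if any(not 0 < t < 1 for t in self.fdr_targets):
            raise ConfigurationError("fdr_targets must lie in (0, 1)")


def write_config(config: RunConfig, path) -> None:
    """Flat ``key: value`` text serialization of a run configuration."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if f.name == "fdr_targets":
            value = ",".join(str(v) for v in value)
        elif f.name == "paths":
            value = ",".join(f"{k}={v}" for k, v in value.items())
        lines.append(f"{f.name}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> RunConfig:
    raw = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected 'key: value'")
        key, _, value = line.partition(":")
        raw[key.strip()] = value.strip()
    kwargs: dict = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name in ("x0", "x0_quantile"):
            kwargs[f.name] = None if value in ("", "None") else float(value)
        elif f.name in ("permutations", "seed"):
            kwargs[f.name] = int(value)
        elif f.name == "alpha":
            kwargs[f.name] = float(value)
        elif f.name == "fdr_targets":
            kwargs[f.name] = tuple(float(v) for v in value.split(",") if v)
        elif f.name == "paths":
            kwargs[f.name] = dict(
                item.split("=", 1) for item in value.split(",") if item
            )
        else:
            kwargs[f.name] = value
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# experiment I/O
# ---------------------------------------------------------------------------

def write_experiment(experiment: ExpressionExperiment, out_prefix, truth=None) -> dict:
    """Write expression/design (and optionally truth) TSVs; returns the paths."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": prefix.with_name(prefix.name + "_expr.tsv"),
        "design": prefix.with_name(prefix.name + "_design.tsv"),
    }
    experiment.expr.to_csv(paths["expr"], sep="\t", index_label="gene_id")
    design = experiment.arm_of_sample.rename("arm").rename_axis("sample_id")
    design.to_frame().to_csv(paths["design"], sep="\t")
    if truth is not None:
        paths["truth"] = prefix.with_name(prefix.name + "_truth.tsv")
        truth.deg_indicator.astype(int).rename("is_deg").rename_axis(
            "gene_id"
        ).to_frame().to_csv(paths["truth"], sep="\t")
    return paths


def load_experiment(expr_path, design_path) -> ExpressionExperiment:
    """Load and validate an experiment from expression + design TSVs.

    Genes with any missing value are dropped (with a logged count); design
    problems raise :class:`DesignError` naming the offending line.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    required = {"sample_id", "arm"}
    if not required.issubset(design.columns):
        raise DesignError(
            f"{design_path}: design needs columns {sorted(required)}, "
            f"got {list(design.columns)}"
        )
    for offset, row in design.iterrows():
        lineno = offset + 2  # header is line 1
        if pd.isna(row["arm"]) or str(row["arm"]).strip() == "":
            raise DesignError(f"{design_path}:{lineno}: empty arm label")
        if row["sample_id"] not in expr.columns:
            raise DesignError(
                f"{design_path}:{lineno}: sample {row['sample_id']!r} "
                "absent from the expression matrix"
            )
    arm_of_sample = design.set_index("sample_id")["arm"]
    n_before = expr.shape[0]
    expr = expr.dropna(axis=0, how="any")
    dropped = n_before - expr.shape[0]
    if dropped:
        logger.info("load_experiment: dropped %d gene(s) with missing values", dropped)
    return ExpressionExperiment(expr=expr, arm_of_sample=arm_of_sample)


def load_truth(path) -> pd.Series:
    truth = pd.read_csv(path, sep="\t", index_col=0)["is_deg"]
    return truth.astype(bool)


def write_results(scores: CombinedScores, path, model: DependenceModel | None = None):
    """Per-gene results TSV; includes null-set membership for Stouffer runs."""
    frame = pd.DataFrame(
        {
            "method": scores.method,
            "statistic": scores.statistic,
            "p_value": scores.p_value,
            "q_value": scores.q_value,
        }
    ).rename_axis("gene_id")
    if model is not None:
        frame["is_null_set_member"] = frame.index.isin(model.null_gene_ids).astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t")
    return frame


def load_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_model_summary(model: DependenceModel, path) -> None:
    """One-row TSV with x0, null-set size, rho entries, and sigma^2."""
    row = {
        "x0": model.x0,
        "n_null_genes": len(model.null_gene_ids),
        "sigma2": model.var_hat,
    }
    cols = list(model.rho_hat.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            row[f"rho[{a},{b}]"] = model.rho_hat.loc[a, b]
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene selection report (user-facing analysis of a real matrix)
# ---------------------------------------------------------------------------

def select_genes(scores: CombinedScores, alpha: float | None = None,
                 fdr: float | None = None) -> pd.Index:
    """Genes significant at a fixed level alpha, or at a q-value threshold."""
    if (alpha is None) == (fdr is None):
        raise ValueError("give exactly one of alpha and fdr")
    if alpha is not None:
        return scores.p_value.index[scores.p_value <= alpha]
    return scores.q_value.index[scores.q_value <= fdr]


# ---------------------------------------------------------------------------
# full benchmark
# ---------------------------------------------------------------------------

def _run_method(method, experiment, n_permutations, seed, perm_cache):
    if method == "stouffer":
        scores, _ = run_stouffer_pipeline(experiment)
        return scores
    if method in ("tippett", "fisher"):
        if not perm_cache:
            perm_cache.update(
                permutation_pvalues_both(
                    experiment, n_permutations=n_permutations,
                    seed=seed + _PERM_SEED_OFFSET,
                )
            )
        return perm_cache[method]
    if method == "dunnett":
        return dunnett_test(experiment, seed=seed + _DUNNETT_SEED_OFFSET)
    raise ConfigurationError(f"unknown method {method!r}")


def run_full_benchmark(
    out_dir,
    seed: int = 0,
    error_families=("normal",),
    replicates=(20,),
    n_datasets: int = 20,
    n_permutations: int = 1000,
    methods=ALL_METHODS,
    fdr_targets=(0.1, 0.2),
    n_genes: int = 4000,
    n_degs: int = 200,
    n_compounds: int = 3,
    effect_size: float = 1.5,
) -> dict[str, pd.DataFrame]:
    """Simulate replicate datasets per condition, run every method, and write
    the rank-statistic, realized-FDR, and ROC report tables.

    Every random stage is seeded deterministically from ``seed``: dataset
    ``i`` simulates with ``seed + i`` and offsets the permutation and
    Monte-Carlo seeds by fixed constants, so repeated runs are byte-identical.
    """
    for fam in error_families:
        if fam not in ERROR_FAMILIES:
            raise ConfigurationError(f"unknown error family {fam!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rank_rows, fdr_rows, roc_rows = [], [], []
    for family in error_families:
        for k in replicates:
            cfg = SimulationConfig(
                n_genes=n_genes, n_degs=n_degs, n_compounds=n_compounds,
                replicates_per_arm=k, effect_size=effect_size,
                error_family=family, seed=seed,
            )
            per_method_p = {m: [] for m in methods}
            truths = []
            per_method_rank = {m: [] for m in methods}
            per_method_fdr = {m: {t: [] for t in fdr_targets} for m in methods}
            for i, (experiment, truth) in enumerate(simulate_many(cfg, n_datasets)):
                truths.append(truth.deg_indicator.to_numpy())
                perm_cache: dict = {}
                for method in methods:
                    scores = _run_method(
                        method, experiment, n_permutations, seed + i, perm_cache
                    )
                    p = scores.p_value.to_numpy()
                    q = scores.q_value.to_numpy()
                    per_method_p[method].append(p)
                    per_method_rank[method].append(
                        deg_rank_stats(p, truths[-1])
                    )
                    for t in fdr_targets:
                        per_method_fdr[method][t].append(
                            true_fdr_at_target(q, truths[-1], t)
                        )
                logger.info(
                    "benchmark: %s k=%d dataset %d/%d done",
                    family, k, i + 1, n_datasets,
                )
            for method in methods:
                agg = aggregate_rank_stats(per_method_rank[method])
                for quantile, row in agg.iterrows():
                    rank_rows.append(
                        dict(error_family=family, replicates=k, method=method,
                             quantile=quantile, mean=row["mean"], sd=row["sd"])
                    )
                for t in fdr_targets:
                    vals = np.asarray(per_method_fdr[method][t])
                    fdr_rows.append(
                        dict(error_family=family, replicates=k, method=method,
                             target=t, mean_true_fdr=vals.mean(),
                             sd_true_fdr=vals.std(ddof=1) if len(vals) > 1 else 0.0)
                    )
                roc = roc_points(per_method_p[method], truths)
                for f, tp in zip(roc.fpr, roc.tpr):
                    roc_rows.append(
                        dict(error_family=family, replicates=k, method=method,
                             fpr=f, tpr=tp)
                    )

    tables = {
        "rank_stats": pd.DataFrame(rank_rows),
        "true_fdr": pd.DataFrame(fdr_rows),
        "roc": pd.DataFrame(roc_rows),
    }
    for name, frame in tables.items():
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.6g")
    logger.info("benchmark: reports written to %s", out_dir)
    return tables
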