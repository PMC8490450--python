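"""Derived expression statistics: differentiation and module scores,
immune high/low grouping with class enrichment, and per-gene differential
expression with Benjamini-Hochberg control."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


def differentiation_score(rho_ref1: pd.Series, rho_ref2: pd.Series) -> pd.Series:
    """Difference of two correlation vectors (e.g. bile duct minus liver).

    A positive score means the sample resembles the first reference more;
    values lie in [-2, 2].
    """
    score = rho_ref1 - rho_ref2
    return score.rename("differentiation_score")


def module_score(
    expr: ExpressionMatrix, gene_set, statistic: str = "median"
) -> pd.Series:
    """Per-sample summary of centered expression over a gene set.

    Genes absent from the matrix are dropped with a warning; an entirely
    absent set is an error. ``statistic`` is "median" (default) or "mean".
    """
    if not expr.is_centered:
        raise ValueError("module_score expects median-centered expression")
    present = [g for g in gene_set if g in expr.values.index]
    missing = set(gene_set) - set(present)
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if missing:
        logger.warning("module score: %d set genes absent from matrix", len(missing))
    sub = expr.values.loc[present]
    if statistic == "median":
        return sub.median(axis=0)
    if statistic == "mean":
        return sub.mean(axis=0)
    raise ValueError(f"unknown statistic {statistic!r}")


def immune_grouping(
    expr: ExpressionMatrix, immune_sets: dict[str, list[str]], statistic: str = "median"
) -> tuple[pd.Series, pd.DataFrame]:
    """Split samples into immune-high / immune-low groups.

    Each immune cell signature is scored with :func:`module_score`; the
    per-sample overall score is the median over the per-set scores, and a
    sample is "high" iff its overall score is at or above the cohort median
    of overall scores (inclusive). Returns (groups, per-set score table).
    """
    if not immune_sets:
        raise ValueError("immune_sets is empty")
    per_set = pd.DataFrame(
        {name: module_score(expr, genes, statistic) for name, genes in immune_sets.items()}
    )
    overall = per_set.median(axis=1)
    split = overall.median()
    groups = pd.Series(
        np.where(overall >= split, "high", "low"), index=overall.index, name="immune_group"
    )
    if groups.nunique() == 1:
        logger.warning("degenerate immune grouping: all samples %s", groups.iloc[0])
    per_set["overall"] = overall
    return groups, per_set


def class_enrichment(
    groups: pd.Series, class_labels: pd.Series, referent_class: str
) -> pd.DataFrame:
    """Fisher-exact enrichment of the "high" group per class versus a referent.

    For every non-referent class a 2x2 table (class vs referent) x (high vs
    low) is tested two-sided. Returns a DataFrame indexed by class with
    odds_ratio and p_value.
    """
    shared = groups.index.intersection(class_labels.index)
    groups = groups.loc[shared]
    class_labels = class_labels.loc[shared]
    if referent_class not in set(class_labels):
        raise ValueError(f"referent class {referent_class!r} has no samples")
    ref_high = int(((class_labels == referent_class) & (groups == "high")).sum())
    ref_low = int(((class_labels == referent_class) & (groups == "low")).sum())
    rows = {}
    for cls in sorted(set(class_labels) - {referent_class}):
        n_high = int(((class_labels == cls) & (groups == "high")).sum())
        n_low = int(((class_labels == cls) & (groups == "low")).sum())
        if n_high + n_low == 0:
            raise ValueError(f"class {cls!r} has no samples")
        odds, p = stats.fisher_exact(
            [[n_high, n_low], [ref_high, ref_low]], alternative="two-sided"
        )
        rows[cls] = {
            "n_high": n_high,
            "n_low": n_low,
            "odds_ratio": odds,
            "p_value": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def differential_expression(
    expr: ExpressionMatrix, samples_a, samples_b
) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups, BH-adjusted.

    Expression is assumed log2-scale, so the fold change is the difference
    of group means. Returns a DataFrame indexed by gene with mean_a,
    mean_b, log2_fold_change, t_statistic, p_value and fdr.
    """
    samples_a, samples_b = list(samples_a), list(samples_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expr.values[samples_a].to_numpy(dtype=float)
    b = expr.values[samples_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # genes constant and equal in both groups produce 0/0; report no evidence
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": mean_a - mean_b,
            "t_statistic": t,
            "p_value": p,
            "fdr": fdr,
        },
        index=expr.values.index,
    )


__all__ = [
    "differentiation_score",
    "module_score",
    "immune_grouping",
    "class_enrichment",
    "differential_expression",
]
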