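"""Class-level copy-number landscape comparison.

Per-feature class means and pairwise difference tracks for genome-wide
plotting, Welch t-tests on continuous values, segment-wise Fisher exact
tests on discretized calls with Benjamini-Hochberg control (the statistical
core of class-specific CNA detection), and expression-copy-number
association per class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CopyNumberTable, ExpressionMatrix

logger = logging.getLogger(__name__)

_DIRECTION_TESTS = {
    "loss": lambda c: c <= -1,
    "gain": lambda c: c >= 1,
    "any": lambda c: c != 0,
}


def _class_members(class_labels: pd.Series, cls: str, columns) -> list[str]:
    members = [s for s in class_labels.index[class_labels == cls] if s in columns]
    if not members:
        raise ValueError(f"class {cls!r} has no samples in the table")
    return members


def _plot_order(features: pd.DataFrame) -> pd.Index:
    if {"chrom", "start"}.issubset(features.columns):
        key = features.assign(
            _c=features["chrom"].astype(str).str.removeprefix("chr")
        )
        key["_cn"] = pd.to_numeric(key["_c"], errors="coerce")
        key = key.sort_values(["_cn", "_c", "start"], kind="mergesort")
        return pd.Index(key["feature_id"])
    return pd.Index(features["feature_id"])


def class_mean_cn(
    cn: CopyNumberTable, class_labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class mean continuous copy number and pairwise difference tracks.

    Returns (means, differences): ``means`` is features x classes ordered
    by genomic coordinate when coordinates are present; ``differences`` has
    one column per ordered class pair named "A-B" (antisymmetric under
    swapping).
    """
    order = _plot_order(cn.features)
    classes = sorted(class_labels.unique())
    means = pd.DataFrame(index=order, columns=classes, dtype=float)
    for cls in classes:
        members = _class_members(class_labels, cls, cn.values.columns)
        means[cls] = cn.values.loc[order, members].mean(axis=1)
    diffs = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            diffs[f"{a}-{b}"] = means[a] - means[b]
    return means, pd.DataFrame(diffs)


def pairwise_cn_ttest(
    cn: CopyNumberTable, class_labels: pd.Series, class_a: str, class_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Welch t-test of continuous CN between two classes."""
    a = _class_members(class_labels, class_a, cn.values.columns)
    b = _class_members(class_labels, class_b, cn.values.columns)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples for a t-test")
    t, p = stats.ttest_ind(
        cn.values[a].to_numpy(), cn.values[b].to_numpy(), axis=1, equal_var=False
    )
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    return pd.DataFrame(
        {"t_statistic": t, "p_value": p, "significant": p < alpha},
        index=cn.values.index,
    )


def segment_fisher(
    cn: CopyNumberTable,
    class_labels: pd.Series,
    class_a: str,
    class_b: str,
    direction: str = "any",
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Segment-wise Fisher exact test of alteration frequency between classes.

    A sample is "altered" on a segment when its discretized call matches
    ``direction`` (loss: call <= -1, gain: call >= 1, any: call != 0). Each
    segment gets a two-sided Fisher exact p on the 2x2 (class x altered)
    table; BH adjustment runs over all tested segments, and ``significant``
    flags fdr < ``fdr_cutoff``.
    """
    if cn.calls is None:
        raise ValueError("segment_fisher requires discretized calls")
    if direction not in _DIRECTION_TESTS:
        raise ValueError(f"direction must be one of {sorted(_DIRECTION_TESTS)}")
    altered = _DIRECTION_TESTS[direction](cn.calls)
    a = _class_members(class_labels, class_a, cn.calls.columns)
    b = _class_members(class_labels, class_b, cn.calls.columns)
    alt_a = altered[a].sum(axis=1).astype(int)
    alt_b = altered[b].sum(axis=1).astype(int)
    n_a, n_b = len(a), len(b)
    pvals, odds = np.empty(len(alt_a)), np.empty(len(alt_a))
    for i, (ka, kb) in enumerate(zip(alt_a.to_numpy(), alt_b.to_numpy())):
        odds[i], pvals[i] = stats.fisher_exact(
            [[ka, n_a - ka], [kb, n_b - kb]], alternative="two-sided"
        )
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "class_a_altered": alt_a,
            "class_b_altered": alt_b,
            "class_a_n": n_a,
            "class_b_n": n_b,
            "odds_ratio": odds,
            "p_value": pvals,
            "fdr": fdr,
            "direction": direction,
            "significant": fdr < fdr_cutoff,
        },
        index=cn.calls.index,
    )
    for col in ("chrom", "start", "end"):
        if col in cn.features.columns:
            out[col] = cn.features.set_index("feature_id")[col]
    logger.info(
        "%s vs %s (%s): %d/%d segments significant at FDR < %g",
        class_a, class_b, direction, int(out["significant"].sum()), len(out), fdr_cutoff,
    )
    return out


def expr_cn_correlation(
    expr: ExpressionMatrix,
    cn: CopyNumberTable,
    gene: str,
    class_labels: pd.Series,
    method: str = "pearson",
    use_calls: bool = False,
) -> pd.DataFrame:
    """Correlation between a gene's expression and its copy number per class.

    Returns one row per class plus an "overall" row with r, p_value and n.
    A class with constant copy number (or constant expression) has an
    undefined correlation and is reported as NA with a warning.
    """
    if gene not in expr.values.index or gene not in cn.values.index:
        raise ValueError(f"gene {gene!r} absent from expression or CN table")
    cn_source = cn.calls if use_calls else cn.values
    if cn_source is None:
        raise ValueError("use_calls=True but the table has no calls")
    shared = [
        s
        for s in class_labels.index
        if s in expr.values.columns and s in cn_source.columns
    ]
    e = expr.values.loc[gene, shared].astype(float)
    c = cn_source.loc[gene, shared].astype(float)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = {}
    groups = {cls: class_labels.index[class_labels == cls] for cls in sorted(class_labels.unique())}
    groups["overall"] = pd.Index(shared)
    for name, members in groups.items():
        members = [s for s in members if s in shared]
        if len(members) < 3:
            rows[name] = {"r": np.nan, "p_value": np.nan, "n": len(members)}
            continue
        ev, cv = e.loc[members], c.loc[members]
        if ev.nunique() < 2 or cv.nunique() < 2:
            logger.warning("constant values in class %r: correlation undefined", name)
            rows[name] = {"r": np.nan, "p_value": np.nan, "n": len(members)}
            continue
        res = corr(ev, cv)
        rows[name] = {"r": float(res.statistic), "p_value": float(res.pvalue), "n": len(members)}
    return pd.DataFrame.from_dict(rows, orient="index")


def gene_alteration_frequency(
    cn: CopyNumberTable, gene: str, class_labels: pd.Series, direction: str = "loss"
) -> pd.Series:
    """Fraction of each class's samples whose call matches ``direction``."""
    if cn.calls is None:
        raise ValueError("gene_alteration_frequency requires discretized calls")
    if gene not in cn.calls.index:
        raise ValueError(f"gene {gene!r} absent from calls")
    altered = _DIRECTION_TESTS[direction](cn.calls.loc[gene])
    out = {}
    for cls in sorted(class_labels.unique()):
        members = _class_members(class_labels, cls, cn.calls.columns)
        out[cls] = float(altered.loc[members].mean())
    return pd.Series(out, name=f"{gene}_{direction}_fraction")


__all__ = [
    "class_mean_cn",
    "pairwise_cn_ttest",
    "segment_fisher",
    "expr_cn_correlation",
    "gene_alteration_frequency",
]
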