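"""ClaNC-style nearest-centroid classification for cross-cohort prediction.

Class-specific marker genes are selected on a labeled, median-centered
training cohort with a moderated class-vs-rest t-like score; prediction on
an external cohort (itself centered on its own samples) is by Spearman
correlation to the training centroids, which keeps the classifier robust to
platform shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CentroidClassifier:
    """Per-class disjoint marker genes plus class-mean centroids."""

    gene_assignments: pd.Series  # gene id -> class
    centroids: pd.DataFrame  # genes (selected union) x classes
    total_genes: int
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gene_assignments.index.duplicated().any():
            raise ValueError("a gene is assigned to more than one class")
        if not set(self.centroids.index) == set(self.gene_assignments.index):
            raise ValueError("centroid genes must equal the selected union")


def train_clanc(
    expr: ExpressionMatrix,
    labels: pd.Series,
    total_genes: int = 150,
    genes_per_class: int | None = None,
) -> CentroidClassifier:
    """Select class-specific genes and build centroids on a training cohort.

    For each gene and class, the score is
    ``(class mean - overall mean) / (pooled within-class sd + s0)`` with
    ``s0`` the median pooled sd over genes (stabilizes zero-variance
    genes). Genes are ranked per class by absolute score and selected
    greedily, highest scores first, each gene going to at most one class
    (ties broken by gene id order). ``total_genes`` is split evenly across
    classes unless ``genes_per_class`` is given; asking for more genes than
    exist selects all, with a warning.
    """
    if not expr.is_centered:
        raise ValueError("train_clanc expects median-centered expression")
    labels = labels.loc[[s for s in labels.index if s in expr.values.columns]]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 samples")
    if genes_per_class is None:
        genes_per_class = total_genes // len(classes)
    X = expr.values[labels.index]
    arr = X.to_numpy(dtype=float)
    overall = arr.mean(axis=1)
    n = arr.shape[1]
    ss_within = np.zeros(arr.shape[0])
    class_means = {}
    for cls in classes:
        members = labels.index[labels == cls]
        sub = X[members].to_numpy(dtype=float)
        class_means[cls] = sub.mean(axis=1)
        ss_within += ((sub - class_means[cls][:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss_within / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    scores = pd.DataFrame(
        {cls: (class_means[cls] - overall) / (pooled_sd + s0) for cls in classes},
        index=X.index,
    )

    want = genes_per_class * len(classes)
    if want > len(X.index):
        logger.warning(
            "requested %d genes but only %d available; selecting all", want, len(X.index)
        )
    # flatten (gene, class, |score|), greedy by descending score
    melted = (
        scores.abs()
        .reset_index(names="gene")
        .melt(id_vars="gene", var_name="cls", value_name="abs_score")
        .sort_values(["abs_score", "gene", "cls"], ascending=[False, True, True], kind="mergesort")
    )
    assigned: dict[str, str] = {}
    remaining = {cls: genes_per_class for cls in classes}
    for row in melted.itertuples(index=False):
        if sum(remaining.values()) == 0:
            break
        if row.gene in assigned or remaining[row.cls] == 0:
            continue
        assigned[row.gene] = row.cls
        remaining[row.cls] -= 1
    gene_assignments = pd.Series(assigned, name="class").sort_index()
    union = list(gene_assignments.index)
    centroids = pd.DataFrame(
        {cls: X.loc[union, labels.index[labels == cls]].mean(axis=1) for cls in classes}
    )
    return CentroidClassifier(
        gene_assignments=gene_assignments,
        centroids=centroids,
        total_genes=len(union),
        classes=classes,
    )


def predict(
    classifier: CentroidClassifier, expr_new: ExpressionMatrix
) -> pd.DataFrame:
    """Predict class labels on a new cohort by centroid correlation.

    The new cohort must carry at least 50% of the classifier's genes and be
    median-centered on its own samples (centered automatically otherwise).
    Each sample gets the class whose centroid it correlates with best
    (Spearman over shared genes); ties go to the first class in name
    order, with a log message. Returns a DataFrame with ``label`` plus one
    correlation column per class.
    """
    from .classify import median_center  # local import to avoid a cycle

    if not expr_new.is_centered:
        expr_new = median_center(expr_new)
    shared = expr_new.values.index.intersection(classifier.centroids.index)
    coverage = len(shared) / len(classifier.centroids.index)
    if coverage < 0.5:
        raise ValueError(
            f"cohort carries only {coverage:.0%} of classifier genes (need >= 50%)"
        )
    X = expr_new.values.loc[shared]
    ranks = np.apply_along_axis(stats.rankdata, 0, X.to_numpy(dtype=float))
    ranks = ranks - ranks.mean(axis=0)
    rho = {}
    for cls in classifier.classes:
        c = stats.rankdata(classifier.centroids.loc[shared, cls].to_numpy(dtype=float))
        c = c - c.mean()
        denom = np.sqrt((ranks**2).sum(axis=0) * (c**2).sum())
        rho[cls] = (ranks * c[:, None]).sum(axis=0) / denom
    cors = pd.DataFrame(rho, index=X.columns)
    ties = cors.eq(cors.max(axis=1), axis=0).sum(axis=1) > 1
    if ties.any():
        logger.info("%d samples tied across centroids; first class in name order wins", int(ties.sum()))
    out = cors.copy()
    out.insert(0, "label", cors.idxmax(axis=1))
    return out


__all__ = ["CentroidClassifier", "train_clanc", "predict"]
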