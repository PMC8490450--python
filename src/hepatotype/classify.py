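"""Reference-anchored correlation subtyping of primary liver tumors.

The procedure partitions a combined cholangiocarcinoma (CCA) / hepatocellular
carcinoma (HCC) expression cohort into CCA, CCA-Like, Blast-Like, HCC and
Normal classes:

1. keep highly and variably expressed genes;
2. median-center each gene across samples;
3. correlate every sample (Spearman) to the CCA centroid — the per-gene
   median of the CCA samples — and call any HCC sample with
   rho >= mean(CCA rho) - sd(CCA rho) "CCA-Like";
4. correlate the remaining tumors to a fetal hepatoblast reference profile
   and call samples in the upper tertile (not already CCA-Like)
   "Blast-Like"; everything else stays "HCC".

Tumor-adjacent normals pass through with the label ``Normal`` and are never
reassigned; they are excluded from the tertile ranking population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PipelineConfig

logger = logging.getLogger(__name__)

LABELS = ("CCA", "CCA-Like", "Blast-Like", "HCC", "Normal")


@dataclass
class CentroidSet:
    """A named per-gene reference profile used as a correlation anchor."""

    name: str
    profile: pd.Series  # indexed by gene id

    def __post_init__(self) -> None:
        if self.profile.index.duplicated().any():
            raise ValueError(f"centroid {self.name!r} has duplicate gene ids")
        if not np.isfinite(self.profile.to_numpy(dtype=float)).all():
            raise ValueError(f"centroid {self.name!r} has non-finite values")


def filter_genes(
    expr: ExpressionMatrix,
    min_expr: float = 1.0,
    min_expr_fraction: float = 0.7,
    top_n_variable: int = 4035,
) -> list[str]:
    """Select highly expressed, variably expressed genes.

    A gene survives when its expression exceeds ``min_expr`` (log2 units) in
    at least ``min_expr_fraction`` of samples; the surviving genes are then
    ranked by median absolute deviation (MAD) across samples and the top
    ``top_n_variable`` returned, most variable first (ties broken by gene
    id). Requesting more genes than survive keeps them all with a warning.
    """
    if expr.is_centered:
        raise ValueError("filter_genes expects uncentered log2 expression")
    v = expr.values
    frac_high = (v > min_expr).mean(axis=1)
    survivors = v.loc[frac_high >= min_expr_fraction]
    mad = stats.median_abs_deviation(survivors.to_numpy(), axis=1, scale=1.0)
    ranked = (
        pd.DataFrame({"gene": survivors.index, "mad": mad})
        .sort_values(["mad", "gene"], ascending=[False, True], kind="mergesort")
    )
    if top_n_variable > len(ranked):
        logger.warning(
            "requested %d variable genes but only %d survive filtering; keeping all",
            top_n_variable,
            len(ranked),
        )
        top_n_variable = len(ranked)
    return ranked["gene"].head(top_n_variable).tolist()


def median_center(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene row at median zero (idempotent)."""
    centered = expr.values.sub(expr.values.median(axis=1), axis=0)
    return ExpressionMatrix(values=centered, is_centered=True)


def _rank_columns(arr: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, arr)


def spearman_to_centroid(expr: ExpressionMatrix, centroid: CentroidSet) -> pd.Series:
    """Spearman rho of every sample against a centroid over shared genes.

    Ties receive average ranks. Requires at least 3 shared genes.
    """
    shared = expr.values.index.intersection(centroid.profile.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} genes shared with centroid {centroid.name!r}; need >= 3"
        )
    x = _rank_columns(expr.values.loc[shared].to_numpy(dtype=float))
    y = stats.rankdata(centroid.profile.loc[shared].to_numpy(dtype=float))
    x = x - x.mean(axis=0)
    y = y - y.mean()
    denom = np.sqrt((x**2).sum(axis=0) * (y**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (x * y[:, None]).sum(axis=0) / denom
    return pd.Series(rho, index=expr.values.columns, name=f"rho_{centroid.name}")


def cca_centroid(expr: ExpressionMatrix, cca_sample_ids) -> CentroidSet:
    """Per-gene median expression of the CCA samples."""
    missing = [s for s in cca_sample_ids if s not in expr.values.columns]
    if missing:
        raise ValueError(f"CCA samples absent from matrix: {missing[:5]}")
    return CentroidSet("CCA", expr.values[list(cca_sample_ids)].median(axis=1))


def classify_cca_like(
    rhos: pd.Series, cca_sample_ids, normal_sample_ids=()
) -> tuple[pd.Series, float]:
    """Label tumors whose CCA correlation reaches mean - 1 SD of CCA's own.

    The threshold is mean(rho over CCA samples) minus the sample standard
    deviation (n-1 denominator); non-CCA tumors with rho >= threshold
    (inclusive) become CCA-Like. CCA samples keep the CCA label; normals
    keep Normal.
    """
    cca_sample_ids = list(cca_sample_ids)
    missing = [s for s in cca_sample_ids if s not in rhos.index]
    if missing:
        raise ValueError(f"CCA samples absent from correlation vector: {missing[:5]}")
    cca_rho = rhos.loc[cca_sample_ids]
    threshold = float(cca_rho.mean() - cca_rho.std(ddof=1))
    labels = pd.Series("HCC", index=rhos.index, dtype=object)
    labels.loc[cca_sample_ids] = "CCA"
    normals = [s for s in normal_sample_ids if s in labels.index]
    labels.loc[normals] = "Normal"
    is_tumor = ~labels.isin(["CCA", "Normal"])
    labels.loc[is_tumor & (rhos >= threshold)] = "CCA-Like"
    return labels, threshold


def classify_blast_like(
    hepatoblast_rhos: pd.Series, labels: pd.Series
) -> tuple[pd.Series, float]:
    """Label non-CCA tumors in the upper tertile of hepatoblast correlation.

    The cutoff is the 66.67th percentile (linear-interpolation quantile) of
    hepatoblast rho over all non-CCA tumor samples; CCA-Like samples count
    toward the ranking population but are never relabeled. Samples at or
    above the cutoff (inclusive) and not CCA-Like become Blast-Like; the
    rest of the tumors stay HCC.
    """
    labels = labels.copy()
    population = labels.index[~labels.isin(["CCA", "Normal"])]
    if len(population) == 0:
        return labels, float("nan")
    pop_rhos = hepatoblast_rhos.loc[population]
    cutoff = float(np.quantile(pop_rhos.to_numpy(dtype=float), 2.0 / 3.0))
    eligible = population[(labels.loc[population] != "CCA-Like")]
    labels.loc[eligible[hepatoblast_rhos.loc[eligible] >= cutoff]] = "Blast-Like"
    return labels, cutoff


def merge_cohorts(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    anchor_sample_ids_a,
    anchor_sample_ids_b,
) -> ExpressionMatrix:
    """Merge two cohorts by anchoring cohort A to cohort B's anchor medians.

    For every shared gene, cohort A is shifted by (median over B anchors -
    median over A anchors), so that after merging the per-gene anchor
    medians of the two cohorts agree. The anchors must be the same
    biological class in both cohorts. The merged matrix is restricted to
    shared genes.
    """
    shared = expr_a.values.index.intersection(expr_b.values.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    overlap = set(expr_a.sample_ids) & set(expr_b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids present in both cohorts: {sorted(overlap)[:5]}")
    a = expr_a.values.loc[shared]
    b = expr_b.values.loc[shared]
    med_a = a[list(anchor_sample_ids_a)].median(axis=1)
    med_b = b[list(anchor_sample_ids_b)].median(axis=1)
    shifted = a.add(med_b - med_a, axis=0)
    return ExpressionMatrix(values=pd.concat([shifted, b], axis=1))


def assign_subtypes(
    expr: ExpressionMatrix,
    cca_sample_ids,
    reference_centroids: dict[str, CentroidSet] | dict[str, pd.Series],
    config: PipelineConfig | None = None,
    normal_sample_ids=(),
) -> pd.DataFrame:
    """Run the full classification and return one row per sample.

    ``reference_centroids`` must contain a ``hepatoblast`` profile and may
    additionally carry ``hepatocyte`` / ``cholangiocyte`` profiles, whose
    correlations are recorded for reporting. Returns a DataFrame indexed by
    sample id with columns label, rho_cca, rho_hepatoblast, rho_hepatocyte,
    rho_cholangiocyte, threshold_used, tertile_cutoff_used.
    """
    config = config or PipelineConfig()
    centroids = {
        name: c if isinstance(c, CentroidSet) else CentroidSet(name, c)
        for name, c in reference_centroids.items()
    }
    if "hepatoblast" not in centroids:
        raise ValueError("reference_centroids must include 'hepatoblast'")

    kept = filter_genes(
        expr, config.min_expr, config.min_expr_fraction, config.top_n_variable
    )
    centered = median_center(expr.subset_genes(kept))

    rho_cca = spearman_to_centroid(centered, cca_centroid(centered, cca_sample_ids))
    labels, threshold = classify_cca_like(rho_cca, cca_sample_ids, normal_sample_ids)

    rho_ref = {}
    for name, centroid in centroids.items():
        rho_ref[name] = spearman_to_centroid(centered, centroid)
    labels, tertile_cutoff = classify_blast_like(rho_ref["hepatoblast"], labels)

    out = pd.DataFrame(
        {
            "label": labels,
            "rho_cca": rho_cca,
            "rho_hepatoblast": rho_ref["hepatoblast"],
            "rho_hepatocyte": rho_ref.get(
                "hepatocyte", pd.Series(np.nan, index=labels.index)
            ),
            "rho_cholangiocyte": rho_ref.get(
                "cholangiocyte", pd.Series(np.nan, index=labels.index)
            ),
        }
    )
    out["threshold_used"] = threshold
    out["tertile_cutoff_used"] = tertile_cutoff
    counts = out["label"].value_counts().to_dict()
    logger.info("subtype counts: %s", counts)
    return out


__all__ = [
    "CentroidSet",
    "LABELS",
    "filter_genes",
    "median_center",
    "spearman_to_centroid",
    "cca_centroid",
    "classify_cca_like",
    "classify_blast_like",
    "merge_cohorts",
    "assign_subtypes",
]
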