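"""Readers, writers and validated containers for every table the pipeline touches.

Conventions
-----------
* All genomic coordinates (variant positions, segment boundaries) are
  1-based and inclusive, following the MAF/SEG convention.
* Expression is stored on the log2(x + 1) scale, genes in rows, samples in
  columns, tab separated on disk.
* Missing expression values are disallowed: the upstream pipeline this
  package models has none, so readers raise instead of imputing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: The 96 canonical pyrimidine-centred trinucleotide substitution labels in
#: conventional (COSMIC-style lexicographic) order: six substitutions
#: C>A, C>G, C>T, T>A, T>C, T>G, each crossed with the 16 flanking pairs
#: ordered A, C, G, T on the 5' side then the 3' side.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
MOTIF_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)


class TableValidationError(ValueError):
    """An input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression on the log2(x+1) scale.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns.
    ``is_centered`` asserts that every gene row has median zero (checked to
    1e-9 at construction).
    """

    values: pd.DataFrame
    is_centered: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise TableValidationError(
                f"non-finite expression at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        if self.is_centered and arr.size:
            med = np.median(arr, axis=1)
            if np.abs(med).max() > 1e-9:
                raise TableValidationError(
                    "is_centered set but some gene medians differ from 0"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.is_centered)


VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "context",
]


@dataclass
class VariantTable:
    """Per-sample somatic single-nucleotide variants.

    ``records`` columns: sample_id, chrom, pos (1-based), ref, alt, gene,
    protein_change, context (3-mer centred on pos; middle base == ref).
    ``rejected`` holds input rows that failed validation together with a
    ``reason`` column.
    """

    records: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VARIANT_COLUMNS + ["reason"])
    )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VariantTable":
        """Validate a raw frame, moving invalid rows to ``rejected``."""
        frame = frame.reindex(columns=VARIANT_COLUMNS).copy()
        frame["ref"] = frame["ref"].astype(str).str.upper()
        frame["alt"] = frame["alt"].astype(str).str.upper()
        reasons = pd.Series("", index=frame.index, dtype=object)

        bad_ref = ~frame["ref"].isin(VALID_BASES)
        bad_alt = ~frame["alt"].isin(VALID_BASES)
        reasons[bad_ref | bad_alt] = "allele not a single A/C/G/T base"
        same = (reasons == "") & (frame["ref"] == frame["alt"])
        reasons[same] = "ref equals alt"

        has_ctx = frame["context"].notna()
        ctx = frame.loc[has_ctx, "context"].astype(str).str.upper()
        bad_len = ctx.str.len() != 3
        mism = (~bad_len) & (ctx.str[1] != frame.loc[has_ctx, "ref"])
        ctx_bad = pd.Series(False, index=frame.index)
        ctx_bad.loc[ctx.index[bad_len | mism]] = True
        reasons[(reasons == "") & ctx_bad] = "context is not a 3-mer centred on ref"
        frame.loc[has_ctx, "context"] = ctx

        ok = reasons == ""
        rejected = frame.loc[~ok].assign(reason=reasons[~ok])
        if len(rejected):
            logger.warning("rejected %d invalid variant rows", len(rejected))
        records = frame.loc[ok].reset_index(drop=True)
        records["pos"] = records["pos"].astype("int64", errors="ignore")
        return cls(records=records, rejected=rejected.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CopyNumberTable:
    """Gene- or segment-level copy number.

    ``features`` carries one row per feature (feature_id plus optional
    chrom/start/end, 1-based inclusive); ``values`` holds continuous copy
    number (features x samples); ``calls`` (optional) holds discretized
    GISTIC-style states in {-2, -1, 0, 1, 2} with identical shape.
    """

    features: pd.DataFrame
    values: pd.DataFrame
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(pd.Index(self.features["feature_id"])):
            raise TableValidationError("values index must equal features.feature_id")
        if self.values.index.duplicated().any():
            raise TableValidationError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise TableValidationError("duplicate sample ids")
        if {"start", "end"}.issubset(self.features.columns):
            se = self.features.dropna(subset=["start", "end"])
            if (se["start"] > se["end"]).any():
                raise TableValidationError("segment start exceeds end")
        if self.calls is not None:
            if self.calls.shape != self.values.shape:
                raise TableValidationError("calls and values shapes differ")
            allowed = {-2, -1, 0, 1, 2}
            if not set(np.unique(self.calls.to_numpy())).issubset(allowed):
                raise TableValidationError("calls outside {-2,-1,0,1,2}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ClinicalTable:
    """Per-sample follow-up: time (days), event indicator, covariates.

    ``data`` is indexed by sample id with columns ``time_days`` (>= 0),
    ``event`` (0/1) and any number of covariate columns (stage, grade,
    class label, continuous scores).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        for col in ("time_days", "event"):
            if col not in d.columns:
                raise TableValidationError(f"clinical table missing column {col!r}")
        if d.index.duplicated().any():
            raise TableValidationError("duplicate sample ids in clinical table")
        if (d["time_days"] < 0).any():
            raise TableValidationError("negative time_days")
        if not d["event"].isin([0, 1]).all():
            raise TableValidationError("event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SignatureCatalog:
    """A 96-motif x K reference signature matrix (COSMIC-SBS style).

    Rows are the canonical motif labels; each column is a probability
    distribution over motifs (non-negative, sums to 1 within 1e-6).
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.weights
        if len(w) != 96:
            raise TableValidationError(f"catalog must have 96 motif rows, got {len(w)}")
        if set(w.index) != set(MOTIF_LABELS):
            missing = sorted(set(MOTIF_LABELS) - set(w.index))
            raise TableValidationError(f"catalog motif labels invalid; missing {missing[:3]}")
        arr = w.to_numpy(dtype=float)
        if (arr < 0).any():
            raise TableValidationError("catalog weights must be non-negative")
        sums = arr.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise TableValidationError("catalog columns must sum to 1")
        # canonical row order
        object.__setattr__(self, "weights", w.loc[list(MOTIF_LABELS)])

    @property
    def signature_names(self) -> list[str]:
        return list(self.weights.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_matrix(path) -> pd.DataFrame:
    header = pd.read_csv(path, sep="\t", header=None, nrows=1).iloc[0, 1:]
    if header.duplicated().any():
        dups = header[header.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample column headers: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise TableValidationError(
                f"non-numeric value at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise TableValidationError(f"missing value at row {row!r}, column {col!r}")
        df[col] = coerced
    return df


def read_expression(path, log_transform: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV of expression estimates.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (computed before any log transform). With
    ``log_transform`` the values are mapped through log2(x + 1).
    """
    df = _read_tsv_matrix(path)
    if df.index.duplicated().any():
        n_before = len(df)
        order = df.mean(axis=1).groupby(level=0).transform("max") == df.mean(axis=1)
        # keep, per gene, the first row attaining the maximal mean
        df = df[order]
        df = df[~df.index.duplicated(keep="first")]
        logger.warning(
            "collapsed %d duplicate gene rows by highest mean expression",
            n_before - len(df),
        )
    if log_transform:
        if (df.to_numpy() < 0).any():
            raise TableValidationError("negative values cannot be log2(x+1) transformed")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(values=df)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


MAF_REQUIRED = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
]
MAF_OPTIONAL = {"Hugo_Symbol": "gene", "HGVSp_Short": "protein_change", "CONTEXT": "context"}


def read_variants(path) -> VariantTable:
    """Read a MAF-compatible somatic variant table (1-based positions).

    Required columns: Tumor_Sample_Barcode, Chromosome, Start_Position,
    Reference_Allele, Tumor_Seq_Allele2. Optional: Hugo_Symbol,
    HGVSp_Short, CONTEXT. Rows that are not valid single-base
    substitutions are moved to ``.rejected`` with a reason.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise TableValidationError(f"MAF missing mandatory column {col!r}")
    out = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "chrom": df["Chromosome"],
            "pos": pd.to_numeric(df["Start_Position"]),
            "ref": df["Reference_Allele"],
            "alt": df["Tumor_Seq_Allele2"],
        }
    )
    for maf_col, col in MAF_OPTIONAL.items():
        out[col] = df[maf_col] if maf_col in df.columns else pd.NA
    return VariantTable.from_frame(out)


def write_variants(variants: VariantTable, path) -> None:
    df = variants.records
    out = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": df["sample_id"],
            "Chromosome": df["chrom"],
            "Start_Position": df["pos"],
            "Reference_Allele": df["ref"],
            "Tumor_Seq_Allele2": df["alt"],
            "Hugo_Symbol": df["gene"],
            "HGVSp_Short": df["protein_change"],
            "CONTEXT": df["context"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_copy_number(values_path, calls_path=None, features_path=None) -> CopyNumberTable:
    """Read feature x sample continuous CN (TSV), optionally with calls.

    ``features_path`` may point to a TSV with feature_id, chrom, start, end
    (1-based inclusive) giving genomic coordinates for plotting order.
    """
    values = _read_tsv_matrix(values_path)
    values.index.name = "feature_id"
    calls = None
    if calls_path is not None:
        calls = _read_tsv_matrix(calls_path).astype(int)
        calls = calls.loc[values.index, values.columns]
    if features_path is not None:
        features = pd.read_csv(features_path, sep="\t")
        features = features.set_index("feature_id").loc[values.index].reset_index()
    else:
        features = pd.DataFrame({"feature_id": values.index})
    return CopyNumberTable(features=features, values=values, calls=calls)


def write_copy_number(cn: CopyNumberTable, values_path, calls_path=None, features_path=None) -> None:
    cn.values.to_csv(values_path, sep="\t")
    if calls_path is not None and cn.calls is not None:
        cn.calls.to_csv(calls_path, sep="\t")
    if features_path is not None:
        cn.features.to_csv(features_path, sep="\t", index=False)


SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Segment_Mean"]


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (1-based inclusive) into a long DataFrame.

    Rows with Start > End are rejected with a logged report; the valid rows
    are returned with columns sample_id, chrom, start, end, value.
    """
    df = pd.read_csv(path, sep="\t")
    for col in SEG_COLUMNS:
        if col not in df.columns:
            raise TableValidationError(f"SEG missing mandatory column {col!r}")
    out = pd.DataFrame(
        {
            "sample_id": df["Sample"],
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int),
            "end": df["End"].astype(int),
            "value": df["Segment_Mean"].astype(float),
        }
    )
    bad = out["start"] > out["end"]
    if bad.any():
        logger.warning("rejected %d SEG rows with start > end", int(bad.sum()))
    return out[~bad].reset_index(drop=True)


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV indexed by sample_id with time_days and event."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(data=df)


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id")


def read_catalog(path) -> SignatureCatalog:
    """Read a 96-motif x K signature catalog TSV (rows labeled "A[C>T]G").

    Columns whose sum deviates from 1 by more than 1e-6 but less than 0.5
    are renormalized with a logged warning; larger deviations are an error.
    """
    df = _read_tsv_matrix(path)
    sums = df.sum(axis=0)
    off = (sums - 1.0).abs()
    if (off >= 0.5).any():
        bad = sums.index[(off >= 0.5).to_numpy()].tolist()
        raise TableValidationError(f"catalog columns far from unit sum: {bad[:5]}")
    to_fix = off > 1e-6
    if to_fix.any():
        logger.warning(
            "renormalizing %d catalog columns with sums off unit by > 1e-6",
            int(to_fix.sum()),
        )
        df = df / sums
    return SignatureCatalog(weights=df)


def write_catalog(catalog: SignatureCatalog, path) -> None:
    catalog.weights.to_csv(path, sep="\t", index_label="motif")


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise TableValidationError(f"duplicate gene set name {parts[0]!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise TableValidationError(f"empty gene set {parts[0]!r}")
            sets[parts[0]] = genes
    return sets


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, loadable from a YAML file."""

    # gene filtering ahead of classification
    min_expr: float = 1.0            # log2 units
    min_expr_fraction: float = 0.7
    top_n_variable: int = 4035
    # subtype rules
    tertile_population: str = "non_cca_tumors"  # ranking population for the blast rule
    # module scores
    score_statistic: str = "median"  # or "mean"
    # copy-number discretization and testing
    call_threshold_low: float = 0.3
    call_threshold_high: float = 1.0
    alpha: float = 0.05
    fdr_cutoff: float = 0.05
    cn_direction: str = "any"
    expr_cn_method: str = "pearson"
    # signature extraction
    nmf_k: int = 6
    nmf_restarts: int = 20
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-8
    # classifier
    clanc_total_genes: int = 150
    # survival
    horizon_days: int = 1826  # five years at 365.25 days, rounded

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise TableValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


def setup_logging(level: int = logging.INFO) -> None:
    """Configure structured console logging for CLI runs."""
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        datefmt="%H:%M:%S",
    )


__all__ = [
    "ExpressionMatrix",
    "VariantTable",
    "CopyNumberTable",
    "ClinicalTable",
    "SignatureCatalog",
    "PipelineConfig",
    "TableValidationError",
    "MOTIF_LABELS",
    "SUBSTITUTIONS",
    "read_expression",
    "write_expression",
    "read_variants",
    "write_variants",
    "read_copy_number",
    "write_copy_number",
    "read_seg",
    "read_clinical",
    "write_clinical",
    "read_catalog",
    "write_catalog",
    "read_gmt",
    "setup_logging",
]
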