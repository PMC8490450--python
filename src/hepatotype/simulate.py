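"""Synthetic multi-omic liver-cancer cohort with planted subclass structure.

Tumors are drawn as noisy mixtures of three latent transcriptional programs
(hepatocyte, cholangiocyte, hepatoblast): CCA and CCA-Like samples weight
the cholangiocyte and hepatoblast programs, Blast-Like weights the
hepatoblast program, and classical HCC weights the hepatocyte program. The
same cohort gets mutation catalogs sampled from planted 96-motif
signatures, segmented copy-number profiles with class-specific events, and
exponential survival times with class-specific hazards — so every pipeline
stage has a known answer.

All generators are pure functions of (config, seed): sample identities,
marker layout and genomic coordinates are derived deterministically from
the configuration, and every random draw goes through one seeded
``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    MOTIF_LABELS,
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
    SignatureCatalog,
    VariantTable,
)

logger = logging.getLogger(__name__)

PROGRAMS = ("hepatocyte", "cholangiocyte", "hepatoblast")
TUMOR_CLASSES = ("CCA", "CCA-Like", "Blast-Like", "HCC")


@dataclass
class CNEvent:
    """A planted arm-level gain or loss affecting a fraction of a class."""

    name: str
    chrom: str
    start: int
    end: int
    effect: float  # signed continuous step, e.g. -0.8 for a loss
    penetrance: dict[str, float]  # class -> fraction of samples carrying it


def _default_weights() -> dict[str, tuple[float, float, float]]:
    # (hepatocyte, cholangiocyte, hepatoblast) program weights per class.
    return {
        "CCA": (0.15, 0.55, 0.30),
        "CCA-Like": (0.15, 0.55, 0.30),
        "Blast-Like": (0.25, 0.10, 0.65),
        "HCC": (0.80, 0.10, 0.10),
        "Normal": (0.90, 0.05, 0.05),
    }


def _default_weight_jitter() -> dict[str, float]:
    # The true CCA class is transcriptionally heterogeneous relative to the
    # CCA-Like tumors that sit near its centre; that spread is what makes
    # the mean - 1 SD rule meaningful.
    return {"CCA": 0.05, "CCA-Like": 0.015, "Blast-Like": 0.015, "HCC": 0.015, "Normal": 0.01}


def _default_exposures() -> dict[str, tuple[float, float, float]]:
    # Exposure over the planted signatures (P1 CpG-like C>T, P2 T>A-rich,
    # P3 aflatoxin-like C>A): biliary-type classes are C>T dominated,
    # hepatocyte-type classes T>A / C>A dominated.
    return {
        "CCA": (0.70, 0.20, 0.10),
        "CCA-Like": (0.65, 0.25, 0.10),
        "Blast-Like": (0.15, 0.45, 0.40),
        "HCC": (0.25, 0.60, 0.15),
        "Normal": (0.34, 0.33, 0.33),
    }


def _default_cn_events() -> list[CNEvent]:
    return [
        CNEvent(
            "3p_loss", "3", 1, 90_000_000, -0.8,
            {"CCA": 0.80, "CCA-Like": 0.45, "Blast-Like": 0.12, "HCC": 0.12},
        ),
        CNEvent(
            "8q_gain", "8", 40_000_000, 146_000_000, 0.8,
            {"CCA": 0.10, "CCA-Like": 0.50, "Blast-Like": 0.60, "HCC": 0.50},
        ),
        CNEvent(
            "6p_gain", "6", 1, 60_000_000, 0.8,
            {"CCA": 0.10, "CCA-Like": 0.40, "Blast-Like": 0.40, "HCC": 0.40},
        ),
        CNEvent(
            "1q_gain", "1", 140_000_000, 248_000_000, 0.8,
            {"CCA": 0.10, "CCA-Like": 0.10, "Blast-Like": 0.60, "HCC": 0.15},
        ),
    ]


def default_planted_signatures() -> pd.DataFrame:
    """Three well-separated planted signatures over the 96 motifs.

    Each concentrates 90% of its mass uniformly on one substitution block
    (P1: C>T, P2: T>A, P3: C>A) with a 10% uniform background, giving
    pairwise cosine similarity well below 0.3. P3 stands in for an
    exposure (aflatoxin-like) C>A signature.
    """
    blocks = {"P1": "C>T", "P2": "T>A", "P3": "C>A"}
    out = pd.DataFrame(0.0, index=list(MOTIF_LABELS), columns=list(blocks))
    for name, sub in blocks.items():
        in_block = np.array([f"[{sub}]" in m for m in MOTIF_LABELS])
        col = np.full(96, 0.1 / 96)
        col[in_block] += 0.9 / in_block.sum()
        out[name] = col
    return out


@dataclass
class SimulationConfig:
    """Everything the cohort generators need; defaults define the study
    conditions the rest of the package is validated under."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "CCA": 40, "CCA-Like": 40, "Blast-Like": 40, "HCC": 40, "Normal": 0,
        }
    )
    n_genes: int = 2000
    markers_per_program: int = 150
    marker_effect: float = 4.0  # log2 units added on a program's markers
    program_sd: float = 3.0  # transcriptome-wide per-program deviation, log2 units
    baseline_range: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.5  # per-gene Gaussian noise, log2 units
    class_weights: dict[str, tuple[float, float, float]] = field(default_factory=_default_weights)
    weight_jitter: dict[str, float] = field(default_factory=_default_weight_jitter)
    # mutations
    mutations_log_mean: float = 4.4  # lognormal parameters of per-sample SNV count
    mutations_log_sd: float = 0.6
    planted_signatures: pd.DataFrame = field(default_factory=default_planted_signatures)
    class_exposures: dict[str, tuple[float, ...]] = field(default_factory=_default_exposures)
    exposure_concentration: float = 50.0  # Dirichlet concentration of per-sample exposures
    r249s_rate: float = 0.5  # fraction of Blast-Like tumors given TP53 p.R249S
    r249s_signature: str = "P3"  # the exposure signature tied to R249S
    r249s_exposure_tilt: float = 0.3
    # copy number
    cn_events: list[CNEvent] = field(default_factory=_default_cn_events)
    cn_jitter_sd: float = 0.1
    call_threshold_low: float = 0.3
    call_threshold_high: float = 1.0
    cn_expression_coupling: float = 1.0  # log2 expression shift per CN unit
    # survival
    baseline_median_days: float = 880.0
    class_hazard_ratios: dict[str, float] = field(
        default_factory=lambda: {"CCA": 1.5, "CCA-Like": 1.7, "Blast-Like": 2.0, "HCC": 1.0}
    )
    weibull_shape: float = 1.0  # 1.0 = exponential
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class sizes must be non-negative")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must lie in [0, 1]")
        for ev in self.cn_events:
            if not all(0 <= p <= 1 for p in ev.penetrance.values()):
                raise ValueError(f"penetrance outside [0, 1] for event {ev.name!r}")
        if self.n_genes < 3 * self.markers_per_program:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than the "
                f"{3 * self.markers_per_program} program marker genes"
            )


@dataclass
class CohortTruth:
    """Ground truth planted by the generators."""

    sample_ids: list[str]
    true_class: pd.Series  # sample -> class
    mixing_weights: pd.DataFrame  # samples x 3 programs, rows sum to 1
    signature_exposures: pd.DataFrame | None = None  # samples x planted signatures
    r249s_carriers: pd.Series | None = None  # sample -> bool
    cn_events: list[CNEvent] = field(default_factory=list)
    hazard_scale: dict[str, float] = field(default_factory=dict)


def class_labels(cfg: SimulationConfig) -> pd.Series:
    """Deterministic sample ids and class labels implied by the config."""
    ids, labels = [], []
    for cls in (*TUMOR_CLASSES, "Normal"):
        for i in range(cfg.n_per_class.get(cls, 0)):
            ids.append(f"{cls.replace('-', '')}_{i + 1:03d}")
            labels.append(cls)
    return pd.Series(labels, index=pd.Index(ids, name="sample_id"), name="true_class")


def gene_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene ids, marker roles and genomic coordinates (1-based inclusive).

    Genes are laid out round-robin across chromosomes 1..22; the first
    blocks of the gene list are the three programs' marker genes, the rest
    background. One background gene on chromosomes 3, 8 and 6 is named
    BAP1, MYC and FOXC1 respectively so that landmark copy-number queries
    have a target.
    """
    m = cfg.markers_per_program
    prefixes = {"hepatocyte": "HEP", "cholangiocyte": "CHOL", "hepatoblast": "BLAST"}
    names, programs = [], []
    for prog in PROGRAMS:
        names += [f"{prefixes[prog]}{i + 1:03d}" for i in range(m)]
        programs += [prog] * m
    n_bg = cfg.n_genes - 3 * m
    names += [f"G{i + 1:04d}" for i in range(n_bg)]
    programs += [""] * n_bg
    idx = np.arange(cfg.n_genes)
    chrom = (idx % 22 + 1).astype(str)
    start = (idx // 22 + 1) * 1_000_000
    df = pd.DataFrame(
        {
            "feature_id": names,
            "program": programs,
            "chrom": chrom,
            "start": start,
            "end": start + 10_000,
        }
    )
    for landmark, ch in (("BAP1", "3"), ("MYC", "8"), ("FOXC1", "6")):
        bg = df.index[(df["program"] == "") & (df["chrom"] == ch)]
        if len(bg):
            df.loc[bg[len(bg) // 2], "feature_id"] = landmark
    if df["feature_id"].duplicated().any():
        raise ValueError("gene id collision in synthetic layout")
    return df


def _program_profiles(cfg: SimulationConfig) -> pd.DataFrame:
    """Noise-free log2 program profiles (genes x 3).

    Every gene carries a continuous program-specific deviation around a
    shared baseline (real cell programs differ transcriptome-wide, not only
    at markers); marker genes additionally get a large dedicated effect.
    The profiles are a fixed deterministic function of the configuration.
    """
    meta = gene_metadata(cfg)
    lo, hi = cfg.baseline_range
    # fixed stream so profiles depend only on cfg, not on the cohort seed
    rng = np.random.default_rng(987654321)
    baseline = rng.uniform(lo, hi, cfg.n_genes)
    deviations = rng.normal(0.0, cfg.program_sd, (cfg.n_genes, 3))
    profiles = pd.DataFrame(
        baseline[:, None] + deviations,
        index=meta["feature_id"],
        columns=list(PROGRAMS),
    )
    for prog in PROGRAMS:
        markers = meta.loc[meta["program"] == prog, "feature_id"]
        profiles.loc[markers, prog] += cfg.marker_effect
    return profiles


def simulate_expression(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, dict[str, pd.Series], CohortTruth]:
    """Draw the expression cohort and its reference centroids.

    Each sample's profile is the weight-mixture of the three program
    profiles plus independent per-gene Gaussian noise (log2 scale). The
    returned centroids are the noise-free programs; ``NBD`` and ``Liver``
    alias the cholangiocyte and hepatocyte programs (microdissected normal
    bile duct and normal liver are the in-vivo counterparts of those two
    programs).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels = class_labels(cfg)
    profiles = _program_profiles(cfg)
    weights = np.empty((len(labels), 3))
    for i, cls in enumerate(labels):
        base = np.asarray(cfg.class_weights[cls], dtype=float)
        w = base + rng.normal(0.0, cfg.weight_jitter.get(cls, 0.0), 3)
        w = np.clip(w, 0.01, None)
        weights[i] = w / w.sum()
    values = profiles.to_numpy() @ weights.T
    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, values.shape)
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=profiles.index, columns=labels.index)
    )
    centroids = {p: profiles[p].copy() for p in PROGRAMS}
    centroids["NBD"] = profiles["cholangiocyte"].rename("NBD")
    centroids["Liver"] = profiles["hepatocyte"].rename("Liver")
    truth = CohortTruth(
        sample_ids=list(labels.index),
        true_class=labels,
        mixing_weights=pd.DataFrame(weights, index=labels.index, columns=list(PROGRAMS)),
        cn_events=list(cfg.cn_events),
        hazard_scale=dict(cfg.class_hazard_ratios),
    )
    return expr, centroids, truth


def simulate_mutations(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[VariantTable, CohortTruth]:
    """Sample per-tumor SNV catalogs from the planted signature mixture.

    Mutation counts are lognormal; each mutation's motif is drawn from the
    sample's exposure-weighted mixture of planted signatures, and the
    trinucleotide context is written inline (no reference genome needed).
    A configurable fraction of Blast-Like tumors receives a TP53 p.R249S
    record and an exposure tilt toward the aflatoxin-like signature.
    """
    seed = cfg.seed if seed is None else seed
    sigs = cfg.planted_signatures
    if list(sigs.index) != list(MOTIF_LABELS):
        sigs = sigs.loc[list(MOTIF_LABELS)]
    col_sums = sigs.sum(axis=0).to_numpy()
    if np.abs(col_sums - 1.0).max() > 1e-6:
        raise ValueError("planted signature columns must sum to 1")
    rng = np.random.default_rng(seed + 1)
    labels = class_labels(cfg)
    sig_names = list(sigs.columns)
    S = sigs.to_numpy()  # 96 x n_sigs
    # pre-split motif labels into (5', ref, alt, 3')
    motif_parts = [(m[0], m[2], m[4], m[6]) for m in MOTIF_LABELS]

    rows: list[dict] = []
    exposures = np.empty((len(labels), len(sig_names)))
    r249s = pd.Series(False, index=labels.index, name="r249s")
    tilt_idx = None
    if cfg.r249s_rate > 0:
        if cfg.r249s_signature not in sig_names:
            raise ValueError(
                f"r249s_signature {cfg.r249s_signature!r} not among planted signatures"
            )
        tilt_idx = sig_names.index(cfg.r249s_signature)
    for i, (sample, cls) in enumerate(labels.items()):
        base = np.asarray(cfg.class_exposures[cls], dtype=float)
        expo = rng.dirichlet(base * cfg.exposure_concentration)
        if cls == "Blast-Like" and rng.random() < cfg.r249s_rate:
            r249s[sample] = True
            tilt = np.zeros_like(expo)
            tilt[tilt_idx] = 1.0
            expo = (1 - cfg.r249s_exposure_tilt) * expo + cfg.r249s_exposure_tilt * tilt
        exposures[i] = expo
        n_mut = max(1, int(round(rng.lognormal(cfg.mutations_log_mean, cfg.mutations_log_sd))))
        motif_counts = rng.multinomial(n_mut, S @ expo)
        for m_idx in np.nonzero(motif_counts)[0]:
            five, ref, alt, three = motif_parts[m_idx]
            for _ in range(motif_counts[m_idx]):
                rows.append(
                    {
                        "sample_id": sample,
                        "chrom": str(rng.integers(1, 23)),
                        "pos": int(rng.integers(1, 100_000_000)),
                        "ref": ref,
                        "alt": alt,
                        "gene": pd.NA,
                        "protein_change": pd.NA,
                        "context": f"{five}{ref}{three}",
                    }
                )
        if r249s[sample]:
            # TP53 p.R249S: G>T on the coding (minus) strand at chr17
            rows.append(
                {
                    "sample_id": sample,
                    "chrom": "17",
                    "pos": 7674220,
                    "ref": "G",
                    "alt": "T",
                    "gene": "TP53",
                    "protein_change": "p.R249S",
                    "context": "AGG",
                }
            )
    table = VariantTable.from_frame(pd.DataFrame(rows))
    truth = CohortTruth(
        sample_ids=list(labels.index),
        true_class=labels,
        mixing_weights=pd.DataFrame(index=labels.index),
        signature_exposures=pd.DataFrame(exposures, index=labels.index, columns=sig_names),
        r249s_carriers=r249s,
    )
    return table, truth


def planted_catalog(cfg: SimulationConfig) -> SignatureCatalog:
    """The planted signatures packaged as a reference catalog."""
    return SignatureCatalog(weights=cfg.planted_signatures.copy())


def _discretize(values: pd.DataFrame, low: float, high: float) -> pd.DataFrame:
    arr = values.to_numpy()
    calls = np.zeros(arr.shape, dtype=int)
    calls[arr >= low] = 1
    calls[arr >= high] = 2
    calls[arr <= -low] = -1
    calls[arr <= -high] = -2
    return pd.DataFrame(calls, index=values.index, columns=values.columns)


def simulate_copy_number(
    cfg: SimulationConfig, seed: int | None = None
) -> CopyNumberTable:
    """Gene-level continuous copy number plus thresholded calls.

    Baseline zero with Gaussian jitter; every configured event adds its
    signed step over the event region for a penetrance-fraction of each
    class's samples. Calls discretize at +-``call_threshold_low`` (-> +-1)
    and +-``call_threshold_high`` (-> +-2).
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed + 2)
    labels = class_labels(cfg)
    meta = gene_metadata(cfg)
    values = pd.DataFrame(
        rng.normal(0.0, cfg.cn_jitter_sd, (cfg.n_genes, len(labels))),
        index=pd.Index(meta["feature_id"]),
        columns=labels.index,
    )
    for ev in cfg.cn_events:
        in_region = (
            (meta["chrom"] == ev.chrom)
            & (meta["start"] <= ev.end)
            & (meta["end"] >= ev.start)
        )
        region_genes = meta.loc[in_region, "feature_id"]
        for cls, pen in ev.penetrance.items():
            members = labels.index[labels == cls]
            if len(members) == 0 or pen == 0:
                continue
            carriers = members[rng.random(len(members)) < pen]
            values.loc[region_genes, carriers] += ev.effect
    calls = _discretize(values, cfg.call_threshold_low, cfg.call_threshold_high)
    return CopyNumberTable(features=meta.drop(columns="program"), values=values, calls=calls)


def simulate_survival(
    cfg: SimulationConfig, truth: CohortTruth, seed: int | None = None
) -> ClinicalTable:
    """Event times with class-specific hazards and uniform censoring.

    Times are Weibull (exponential at shape 1) with per-class hazard =
    baseline x class hazard ratio. Each sample is independently censored
    with probability ``censoring_rate``; a censored sample's time is
    uniform on (0, T). Stage and grade covariates are drawn independently.
    Normal samples carry no follow-up and are excluded.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed + 3)
    lam0 = np.log(2.0) / cfg.baseline_median_days
    rows = {}
    for sample, cls in truth.true_class.items():
        if cls == "Normal":
            continue
        hr = cfg.class_hazard_ratios.get(cls, 1.0)
        u = rng.random()
        t = (-np.log(u) / (lam0 * hr)) ** (1.0 / cfg.weibull_shape)
        event = 1
        if rng.random() < cfg.censoring_rate:
            event = 0
            t = t * rng.random()
        rows[sample] = {
            "time_days": float(t),
            "event": event,
            "class": cls,
            "stage": int(rng.integers(1, 5)),
            "grade": int(rng.integers(1, 4)),
        }
    return ClinicalTable(data=pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class CohortBundle:
    """One coherent multi-omic synthetic cohort."""

    expression: ExpressionMatrix
    centroids: dict[str, pd.Series]
    variants: VariantTable
    copy_number: CopyNumberTable
    clinical: ClinicalTable
    truth: CohortTruth


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None) -> CohortBundle:
    """Generate the full bundle with expression coupled to copy number.

    Expression receives ``cn_expression_coupling`` log2 units per
    continuous copy-number unit, so dosage-driven expression-CN
    correlation exists at planted-event genes.
    """
    seed = cfg.seed if seed is None else seed
    expr, centroids, truth = simulate_expression(cfg, seed)
    variants, mut_truth = simulate_mutations(cfg, seed)
    truth.signature_exposures = mut_truth.signature_exposures
    truth.r249s_carriers = mut_truth.r249s_carriers
    cn = simulate_copy_number(cfg, seed)
    if cfg.cn_expression_coupling != 0.0:
        coupled = expr.values.add(
            cfg.cn_expression_coupling * cn.values.loc[expr.values.index], fill_value=0.0
        )
        expr = ExpressionMatrix(values=coupled)
    clinical = simulate_survival(cfg, truth, seed)
    return CohortBundle(
        expression=expr,
        centroids=centroids,
        variants=variants,
        copy_number=cn,
        clinical=clinical,
        truth=truth,
    )


__all__ = [
    "PROGRAMS",
    "TUMOR_CLASSES",
    "CNEvent",
    "SimulationConfig",
    "CohortTruth",
    "CohortBundle",
    "class_labels",
    "gene_metadata",
    "default_planted_signatures",
    "planted_catalog",
    "simulate_expression",
    "simulate_mutations",
    "simulate_copy_number",
    "simulate_survival",
    "simulate_cohort",
]
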