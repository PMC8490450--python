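"""Trinucleotide mutational-signature analysis.

Single-base substitutions are collapsed onto the 96 canonical
pyrimidine-centred contexts (6 substitutions x 16 flanking pairs), counted
per sample, summarised per tumor class, decomposed into de novo signatures
by non-negative matrix factorization (Frobenius-loss multiplicative
updates), and matched against a COSMIC-SBS-style reference catalog by
cosine similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MOTIF_LABELS, SignatureCatalog, VariantTable

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(ref: str, alt: str, context: str) -> str:
    """Collapse a substitution onto its pyrimidine-centred motif label.

    ``context`` is the 3-mer around the variant with the reference base in
    the middle. Purine reference bases are reverse-complemented (both the
    substitution and the flanks) so that the central base is C or T; the
    label is formatted like ``"A[C>T]G"``. Ambiguous bases raise a
    ValueError (callers skip and report such records).
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} is not a 3-mer centred on {ref!r}")
    if any(b not in "ACGT" for b in (ref, alt, *context)) or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt} in context {context!r}")
    if ref in "AG":  # purine: report the reverse-complement strand
        context = _revcomp(context)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def context_from_fasta(fasta, chrom: str, pos: int) -> str:
    """Fetch the 3-mer around a 1-based position from a pyfaidx Fasta."""
    return str(fasta[chrom][pos - 2 : pos + 1]).upper()


@dataclass
class MotifMatrix:
    """Samples x 96 motif counts with per-sample frequencies on demand."""

    counts: pd.DataFrame  # samples x 96, canonical column order
    skipped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(MOTIF_LABELS):
            raise ValueError("motif columns must be the 96 canonical labels in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("motif counts must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        """Counts normalized per sample; zero-mutation samples stay zero."""
        tot = self.totals.replace(0, np.nan)
        return self.counts.div(tot, axis=0).fillna(0.0)


def count_motifs(variants: VariantTable, fasta=None) -> MotifMatrix:
    """Histogram each sample's SNVs over the 96 canonical motifs.

    Contexts come from the variant table's inline ``context`` column, or
    from ``fasta`` (a pyfaidx Fasta) when missing. Records without a
    usable context are skipped and reported; samples whose records are all
    skipped are retained with zero counts.
    """
    records = variants.records.copy()
    samples = sorted(records["sample_id"].unique())
    counts = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"), columns=list(MOTIF_LABELS)
    )
    missing_ctx = records["context"].isna()
    if fasta is not None and missing_ctx.any():
        records.loc[missing_ctx, "context"] = [
            context_from_fasta(fasta, row.chrom, int(row.pos))
            for row in records.loc[missing_ctx].itertuples()
        ]
    # at most 192 valid (ref, alt, context) combinations: map through a cache
    keys = list(zip(records["ref"], records["alt"], records["context"].astype(str)))
    label_cache: dict[tuple, str | None] = {}
    labels, reasons = [], []
    for key in keys:
        if key not in label_cache:
            try:
                label_cache[key] = canonical_motif(*key)
            except ValueError as exc:
                label_cache[key] = None
                label_cache[(*key, "reason")] = str(exc)
        lab = label_cache[key]
        labels.append(lab)
        reasons.append(None if lab else label_cache.get((*key, "reason"), "invalid"))
    records["motif"], records["reason"] = labels, reasons
    kept = records[records["motif"].notna()]
    tallies = kept.groupby(["sample_id", "motif"]).size()
    for (sample, label), n in tallies.items():
        counts.at[sample, label] += int(n)
    skipped = records[records["motif"].isna()].drop(columns="motif")
    if len(skipped):
        logger.warning("count_motifs skipped %d records", len(skipped))
    return MotifMatrix(counts=counts, skipped=skipped.reset_index(drop=True))


def class_motif_profile(motifs: MotifMatrix, class_labels: pd.Series) -> pd.DataFrame:
    """Median motif frequency per class (classes x 96, Lego-plot layout)."""
    freq = motifs.frequencies
    shared = freq.index.intersection(class_labels.index)
    class_labels = class_labels.loc[shared]
    rows = {}
    for cls in sorted(class_labels.unique()):
        members = class_labels.index[class_labels == cls]
        if len(members) == 0:
            raise ValueError(f"class {cls!r} is empty")
        rows[cls] = freq.loc[members].median(axis=0)
    if not rows:
        raise ValueError("no classes to profile")
    return pd.DataFrame(rows).T[list(MOTIF_LABELS)]


@dataclass
class SignatureModel:
    """De novo signatures (96 x k, columns sum to 1) and sample exposures."""

    signatures: pd.DataFrame  # 96 x k
    exposures: pd.DataFrame  # k x samples
    k: int
    n_restarts: int
    seed: int
    reconstruction_error: float
    error_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if (self.signatures.to_numpy() < -1e-12).any() or (
            self.exposures.to_numpy() < -1e-12
        ).any():
            raise ValueError("signatures and exposures must be non-negative")
        sums = self.signatures.sum(axis=0).to_numpy()
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("signature columns must sum to 1")


def _nmf_multiplicative(V: np.ndarray, k: int, rng, max_iter: int, tol: float):
    """One NMF run: Frobenius-loss multiplicative updates with error tracking."""
    eps = 1e-12
    m, n = V.shape
    scale = np.sqrt(V.mean() / max(k, 1))
    W = scale * (rng.random((m, k)) + 0.1)
    H = scale * (rng.random((k, n)) + 0.1)
    err = np.linalg.norm(V - W @ H)
    trajectory = [err]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        new_err = np.linalg.norm(V - W @ H)
        trajectory.append(new_err)
        if err - new_err < tol * max(err, eps):
            err = new_err
            break
        err = new_err
    return W, H, err, np.asarray(trajectory)


def extract_signatures(
    motifs: MotifMatrix,
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    use_frequencies: bool = True,
) -> SignatureModel:
    """De novo signature extraction by non-negative factorization.

    The per-sample frequency matrix (96 x samples; counts with
    ``use_frequencies=False``) is factorized with multiplicative updates;
    the best of ``n_restarts`` random initialisations by Frobenius
    reconstruction error wins. Signatures are column-normalized to unit sum
    (exposures rescaled compensatingly) and ordered by total exposure,
    descending. Deterministic given ``seed``. The per-iteration error
    trajectory of the winning run is kept and verified non-increasing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_samples = len(motifs.sample_ids)
    if k > min(96, n_samples):
        raise ValueError(f"k={k} exceeds achievable rank min(96, {n_samples})")
    data = motifs.frequencies if use_frequencies else motifs.counts.astype(float)
    V = data.to_numpy(dtype=float).T  # 96 x samples
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        W, H, err, traj = _nmf_multiplicative(V, k, rng, max_iter, tol)
        if best is None or err < best[2]:
            best = (W, H, err, traj)
    W, H, err, traj = best
    # monotone descent up to float noise, judged on the problem's error scale
    increases = np.diff(traj)
    if increases.size and increases.max() > 1e-10 * max(traj[0], 1e-12):
        raise RuntimeError("multiplicative updates increased the reconstruction error")
    col_sums = W.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    W = W / col_sums
    H = H * col_sums[:, None]
    order = np.argsort(-H.sum(axis=1), kind="stable")
    W, H = W[:, order], H[order]
    names = [f"S{i + 1}" for i in range(k)]
    return SignatureModel(
        signatures=pd.DataFrame(W, index=list(MOTIF_LABELS), columns=names),
        exposures=pd.DataFrame(H, index=names, columns=motifs.sample_ids),
        k=k,
        n_restarts=n_restarts,
        seed=seed,
        reconstruction_error=float(err),
        error_trajectory=traj,
    )


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (|u| |v|); in [0, 1] for non-negative inputs."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(u @ v / (nu * nv))


def match_catalog(model: SignatureModel, catalog: SignatureCatalog) -> pd.DataFrame:
    """Pairwise cosine table between de novo and catalog signatures (k x K).

    Motif rows are aligned by label, never by position; a label mismatch is
    an error (caught by the catalog container).
    """
    cat = catalog.weights.loc[list(MOTIF_LABELS)]
    sig = model.signatures.loc[list(MOTIF_LABELS)]
    out = pd.DataFrame(
        index=sig.columns, columns=cat.columns, dtype=float
    )
    for s in sig.columns:
        for c in cat.columns:
            out.at[s, c] = cosine_similarity(sig[s], cat[c])
    return out


def sample_catalog_similarity(
    motifs: MotifMatrix, catalog: SignatureCatalog, class_labels: pd.Series
) -> pd.DataFrame:
    """Per-class median cosine similarity to every catalog signature.

    Zero-mutation samples have no defined profile and are excluded with a
    warning. Returns classes x catalog signatures.
    """
    freq = motifs.frequencies
    usable = motifs.totals > 0
    if (~usable).any():
        logger.warning(
            "excluding %d zero-mutation samples from cosine similarity",
            int((~usable).sum()),
        )
    freq = freq.loc[usable]
    shared = freq.index.intersection(class_labels.index)
    class_labels = class_labels.loc[shared]
    cat = catalog.weights.loc[list(MOTIF_LABELS)].to_numpy()
    F = freq.loc[shared, list(MOTIF_LABELS)].to_numpy()
    sims = (F @ cat) / (
        np.linalg.norm(F, axis=1)[:, None] * np.linalg.norm(cat, axis=0)[None, :]
    )
    per_sample = pd.DataFrame(sims, index=shared, columns=catalog.signature_names)
    rows = {}
    for cls in sorted(class_labels.unique()):
        members = class_labels.index[class_labels == cls]
        rows[cls] = per_sample.loc[members].median(axis=0)
    return pd.DataFrame(rows).T


def exposure_by_class(model: SignatureModel, class_labels: pd.Series) -> pd.DataFrame:
    """Per-class median of per-sample normalized exposures (classes x k).

    Exposures are normalized per sample to sum 1; all-zero-exposure
    samples are excluded with a warning.
    """
    expo = model.exposures.T  # samples x k
    totals = expo.sum(axis=1)
    usable = totals > 0
    if (~usable).any():
        logger.warning("excluding %d zero-exposure samples", int((~usable).sum()))
    norm = expo.loc[usable].div(totals.loc[usable], axis=0)
    shared = norm.index.intersection(class_labels.index)
    class_labels = class_labels.loc[shared]
    rows = {}
    for cls in sorted(class_labels.unique()):
        members = class_labels.index[class_labels == cls]
        rows[cls] = norm.loc[members].median(axis=0)
    return pd.DataFrame(rows).T


def variant_group_similarity_test(
    motifs: MotifMatrix,
    catalog: SignatureCatalog,
    signature_id: str,
    group_a,
    group_b,
) -> tuple[float, float]:
    """Welch t-test of per-sample cosine similarity to one catalog signature.

    Used e.g. to ask whether TP53 p.R249S tumors sit closer to the
    aflatoxin signature than TP53-wildtype tumors. Returns (t, two-sided p).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    target = catalog.weights[signature_id].to_numpy()
    freq = motifs.frequencies[list(MOTIF_LABELS)]

    def sims(samples):
        vals = []
        for s in samples:
            v = freq.loc[s].to_numpy()
            if v.sum() == 0:
                logger.warning("excluding zero-mutation sample %r", s)
                continue
            vals.append(cosine_similarity(v, target))
        return np.asarray(vals)

    a, b = sims(group_a), sims(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("fewer than 2 usable samples in a group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


__all__ = [
    "MotifMatrix",
    "SignatureModel",
    "canonical_motif",
    "context_from_fasta",
    "count_motifs",
    "class_motif_profile",
    "extract_signatures",
    "cosine_similarity",
    "match_catalog",
    "sample_catalog_similarity",
    "exposure_by_class",
    "variant_group_similarity_test",
]
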