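"""Sample- and variant-level genotype quality control.

Implements the standard array-QC battery for an association cohort:
sample call-rate and heterozygosity filters, method-of-moments kinship
with greedy pruning of related pairs, PCA for ancestry outliers and the
first two ancestry covariates (MDSC1/MDSC2), and the variant-level
filters (per-batch missingness, differential missingness across
genotyping batches, Hardy-Weinberg equilibrium, strand-ambiguous
variants at high MAF, duplicate-variant deduplication).

Dosages are stored as a float matrix (individuals x variants) with values
in {0, 1, 2} and NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class VariantInfo:
    """Metadata for one biallelic variant (positions 1-based, hg19 by default)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")
    call_rate: float = 1.0
    info_score: float = 1.0  # genotyped variants default to perfect imputation quality
    build: str = "hg19"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele or not self.alt_allele or self.ref_allele == self.alt_allele:
            raise ValueError(f"alleles must be non-empty and distinct: {self.ref_allele!r}/{self.alt_allele!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    @property
    def is_ambiguous(self) -> bool:
        """A/T or C/G SNP: strand cannot be resolved from the alleles alone."""
        pair = frozenset((self.ref_allele.upper(), self.alt_allele.upper()))
        return pair in (frozenset("AT"), frozenset("CG"))


@dataclass
class GenotypeMatrix:
    individual_ids: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray  # (n_individuals, n_variants), NaN = missing

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.variants):
            raise ValueError("dosage matrix shape inconsistent with ids/variants")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_maf(self) -> np.ndarray:
        """Minor-allele frequency per variant from the observed dosages (alt-allele folded)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def variant_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def refresh_metadata(self) -> None:
        """Recompute per-variant MAF and call rate from the current dosage matrix."""
        maf = self.variant_maf()
        miss = self.variant_missingness()
        for v, m, c in zip(self.variants, maf, miss):
            v.maf = float(m)
            v.call_rate = float(1.0 - c)

    def subset(self, sample_idx: Sequence[int] | None = None, variant_idx: Sequence[int] | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_individuals) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosages=self.dosages[np.ix_(si, vi)].copy(),
        )


@dataclass
class QCThresholds:
    """Exclusion thresholds; defaults follow common array-QC practice."""

    sample_missingness_max: float = 0.05
    het_sd_bound: float = 6.0
    kinship_max: float = 0.125  # third-degree relative cut-off
    variant_missingness_max: float = 0.05
    diff_missingness_p: float = 1e-10
    hwe_p: float = 5e-8
    ambiguous_maf_min: float = 0.4
    pca_outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in ("sample_missingness_max", "diff_missingness_p", "hwe_p", "ambiguous_maf_min", "variant_missingness_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.het_sd_bound <= 0 or self.kinship_max <= 0 or self.pca_outlier_sd <= 0:
            raise ValueError("bounds must be positive")


@dataclass
class QCReport:
    excluded_samples: dict[str, str] = field(default_factory=dict)
    excluded_variants: dict[str, str] = field(default_factory=dict)
    pcs: pd.DataFrame | None = None  # kept individuals x PCs; PC1/PC2 double as MDSC1/MDSC2
    summary_counts: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def exclude_sample(self, sid: str, reason: str) -> None:
        # first matching rule wins: one primary reason per exclusion
        self.excluded_samples.setdefault(sid, reason)

    def exclude_variant(self, key: str, reason: str) -> None:
        self.excluded_variants.setdefault(key, reason)

    @property
    def mdsc(self) -> pd.DataFrame:
        if self.pcs is None:
            raise ValueError("PCA has not been run")
        out = self.pcs[["PC1", "PC2"]].copy()
        out.columns = ["MDSC1", "MDSC2"]
        return out


def sample_qc(matrix: GenotypeMatrix, thresholds: QCThresholds, report: QCReport | None = None) -> QCReport:
    """Sample filters: call missingness, then heterozygosity-rate outliers.

    Heterozygosity (share of non-missing genotypes that are heterozygous)
    is referenced to the mean and SD of the samples that survived the
    missingness filter, and samples beyond +/- ``het_sd_bound`` SD are
    excluded.  A chromosome-X sex consistency check needs sex-chromosome
    data that this pipeline does not model; it is recorded as skipped.
    """
    if matrix.n_individuals == 0 or matrix.n_variants == 0:
        raise ValueError("empty genotype matrix")
    report = report or QCReport()
    miss = matrix.sample_missingness()
    for sid, m in zip(matrix.individual_ids, miss):
        if m > thresholds.sample_missingness_max:
            report.exclude_sample(sid, "missingness")

    keep = np.array([sid not in report.excluded_samples for sid in matrix.individual_ids])
    if not keep.any():
        raise ValueError("empty cohort: all samples excluded by missingness filter")
    obs = ~np.isnan(matrix.dosages)
    het = np.where(obs, matrix.dosages == 1.0, False).sum(axis=1) / obs.sum(axis=1)
    mu, sd = het[keep].mean(), het[keep].std(ddof=0)
    if sd > 0:
        lo, hi = mu - thresholds.het_sd_bound * sd, mu + thresholds.het_sd_bound * sd
        for sid, h, k in zip(matrix.individual_ids, het, keep):
            if k and not (lo <= h <= hi):
                report.exclude_sample(sid, "heterozygosity")
    report.notes.append("sex-check skipped: no chrX data in scope")
    if all(sid in report.excluded_samples for sid in matrix.individual_ids):
        raise ValueError("empty cohort: all samples excluded")
    return report


def estimate_kinship(matrix: GenotypeMatrix, return_self_norms: bool = False):
    """Pairwise relatedness (pi-hat scale) by the method of moments.

    Dosages are centred at twice the allele frequency and scaled by the
    binomial SD; the average cross-product over pairwise-complete variants
    estimates the relationship coefficient (0 for unrelated pairs, 0.5 for
    parent-offspring or full sibs, ~1 for duplicates).  Values are clamped
    to [0, 1] and the self-relatedness is 1 by definition.
    """
    if matrix.n_individuals < 2:
        raise ValueError("kinship requires at least two samples")
    p = matrix.alt_freq()
    ok = (p > 0) & (p < 1)
    if not ok.any():
        raise ValueError("no polymorphic variants for kinship estimation")
    X = matrix.dosages[:, ok]
    p = p[ok]
    obs = ~np.isnan(X)
    Z = (np.nan_to_num(X) - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z[~obs] = 0.0
    num = Z @ Z.T
    den = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = num / den
    K = np.nan_to_num(K)
    self_norms = pd.Series(np.diag(K).copy(), index=matrix.individual_ids)
    K = np.clip(K, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    frame = pd.DataFrame(K, index=matrix.individual_ids, columns=matrix.individual_ids)
    if return_self_norms:
        return frame, self_norms
    return frame


def kinship_filter(
    kinship: pd.DataFrame,
    cutoff: float = 0.125,
    sample_missingness: pd.Series | None = None,
    skip: set[str] | frozenset[str] = frozenset(),
) -> list[str]:
    """Greedy pruning of related pairs above ``cutoff``.

    Processes flagged pairs in deterministic id order, removing from each
    the member with the higher missingness (ties broken towards the
    lexicographically larger id) until no pair remains above the cut-off.
    Pairs involving a sample in ``skip`` are ignored (used for ancestry
    outliers, whose shifted allele frequencies distort pairwise estimates;
    they are excluded by PCA instead).
    """
    ids = list(kinship.index)
    if sample_missingness is None:
        sample_missingness = pd.Series(0.0, index=ids)
    K = kinship.to_numpy()
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    pairs = []
    for i in range(len(ids)):
        if ids[i] in skip:
            continue
        for j in range(i + 1, len(ids)):
            if K[i, j] > cutoff and ids[j] not in skip:
                pairs.append((ids[i], ids[j]))
    pairs.sort()
    removed: set[str] = set()
    for a, b in pairs:
        if a in removed or b in removed:
            continue
        ma, mb = sample_missingness.get(a, 0.0), sample_missingness.get(b, 0.0)
        if ma > mb:
            removed.add(a)
        elif mb > ma:
            removed.add(b)
        else:
            removed.add(max(a, b))
    return sorted(removed)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df) goodness-of-fit test of Hardy-Weinberg equilibrium.

    Expected genotype counts p^2, 2pq, q^2 are formed from the observed
    allele frequency.  Monomorphic variants fit HWE trivially (p = 1).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotypes observed")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds,
    batch_labels: Sequence[str] | None = None,
    report: QCReport | None = None,
) -> QCReport:
    """Variant filters, applied in order so each exclusion has one primary reason.

    1. missingness > threshold within any genotyping batch;
    2. differential missingness across batches (chi-square on the
       missing/observed contingency table);
    3. Hardy-Weinberg disequilibrium;
    4. strand-ambiguous (A/T, C/G) variants with MAF above the bound;
    5. duplicated (chrom, pos, allele-set) records, keeping the copy with
       the lowest missingness.
    """
    report = report or QCReport()
    n = matrix.n_individuals
    labels = np.asarray(["batch1"] * n if batch_labels is None else list(batch_labels))
    if labels.shape[0] != n:
        raise ValueError(f"batch_labels length {labels.shape[0]} != n_individuals {n}")
    batches = sorted(set(labels))
    miss_mat = np.isnan(matrix.dosages)

    per_batch_miss = np.stack([miss_mat[labels == b].mean(axis=0) for b in batches])
    for j, v in enumerate(matrix.variants):
        if (per_batch_miss[:, j] > thresholds.variant_missingness_max).any():
            report.exclude_variant(v.key, "missingness")

    if len(batches) > 1:
        n_per_batch = np.array([(labels == b).sum() for b in batches], dtype=float)
        n_missing = np.stack([miss_mat[labels == b].sum(axis=0) for b in batches]).astype(float)
        for j, v in enumerate(matrix.variants):
            if v.key in report.excluded_variants:
                continue
            table = np.column_stack([n_missing[:, j], n_per_batch - n_missing[:, j]])
            if (table.sum(axis=0) == 0).any():
                continue  # no missing calls anywhere (or none observed): test undefined
            pval = stats.chi2_contingency(table, correction=False).pvalue
            if pval < thresholds.diff_missingness_p:
                report.exclude_variant(v.key, "differential_missingness")

    D = matrix.dosages
    for j, v in enumerate(matrix.variants):
        if v.key in report.excluded_variants:
            continue
        col = D[:, j]
        col = col[~np.isnan(col)]
        counts = [(col == g).sum() for g in (0.0, 1.0, 2.0)]
        if sum(counts) and hwe_test(*counts) < thresholds.hwe_p:
            report.exclude_variant(v.key, "hwe")

    maf = matrix.variant_maf()
    for j, v in enumerate(matrix.variants):
        if v.key in report.excluded_variants:
            continue
        if v.is_ambiguous and maf[j] > thresholds.ambiguous_maf_min:
            report.exclude_variant(v.key, "ambiguous")

    missingness = matrix.variant_missingness()
    best: dict[tuple, int] = {}
    for j, v in enumerate(matrix.variants):
        if v.key in report.excluded_variants:
            continue
        sig = (v.chrom, v.pos, frozenset((v.ref_allele, v.alt_allele)))
        if sig not in best:
            best[sig] = j
        else:
            k = best[sig]
            if missingness[j] < missingness[k]:
                report.exclude_variant(matrix.variants[k].key + f"#{k}", "duplicate")
                best[sig] = j
            else:
                report.exclude_variant(v.key + f"#{j}", "duplicate")
    return report


def pca_project(matrix: GenotypeMatrix, k: int = 2, outlier_sd: float = 6.0) -> tuple[pd.DataFrame, list[str]]:
    """Principal components of the standardized dosage matrix, plus outlier flags.

    Missing dosages are mean-imputed per variant and each variant scaled by
    its binomial SD sqrt(2 p (1-p)); the returned component matrix has
    orthonormal columns.  Samples beyond ``outlier_sd`` SDs from the cohort
    mean on any of the first k components are flagged as ancestry outliers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    p = matrix.alt_freq()
    ok = (p > 0) & (p < 1)
    X = matrix.dosages[:, ok]
    p = p[ok]
    X = np.where(np.isnan(X), 2 * p, X)
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z -= Z.mean(axis=0)
    C = Z @ Z.T
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > evals[0] * 1e-12).sum()) if evals[0] > 0 else 0
    if k > rank:
        raise ValueError(f"requested {k} components but matrix rank is {rank}")
    U = evecs[:, :k]
    # fix sign for determinism: largest-magnitude loading positive
    for j in range(k):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    pcs = pd.DataFrame(U, index=matrix.individual_ids, columns=[f"PC{i + 1}" for i in range(k)])
    mu, sd = U.mean(axis=0), U.std(axis=0, ddof=0)
    flags = (np.abs(U - mu) > outlier_sd * sd).any(axis=1)
    outliers = [sid for sid, f in zip(matrix.individual_ids, flags) if f]
    return pcs, outliers


def run_qc(
    matrix: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    batch_labels: Sequence[str] | None = None,
    n_pcs: int = 2,
) -> tuple[GenotypeMatrix, QCReport]:
    """Full QC chain: sample filters -> kinship pruning -> ancestry outliers ->
    variant filters -> MAF refresh -> final PCA on the clean cohort.

    Returns the filtered matrix (with refreshed per-variant metadata) and a
    report holding every exclusion with its primary reason, the per-sample
    principal components (PC1/PC2 exported as MDSC1/MDSC2) and stage counts.
    """
    thresholds = thresholds or QCThresholds()
    report = QCReport()
    report.summary_counts["input_samples"] = matrix.n_individuals
    report.summary_counts["input_variants"] = matrix.n_variants

    sample_qc(matrix, thresholds, report)
    keep_idx = [i for i, sid in enumerate(matrix.individual_ids) if sid not in report.excluded_samples]
    current = matrix.subset(sample_idx=keep_idx)
    labels = None if batch_labels is None else [batch_labels[i] for i in keep_idx]

    # Relatedness before PCA, so a duplicate pair cannot masquerade as its
    # own principal axis.  Samples whose self-variance is inflated (>1.5x)
    # sit off the cohort's allele-frequency profile; their pairwise
    # estimates are distorted, so they are left to the PCA outlier step.
    kin, self_norms = estimate_kinship(current, return_self_norms=True)
    freq_outliers = set(self_norms.index[self_norms > 1.5])
    miss = pd.Series(current.sample_missingness(), index=current.individual_ids)
    for sid in kinship_filter(kin, thresholds.kinship_max, miss, skip=frozenset(freq_outliers)):
        report.exclude_sample(sid, "kinship")
    keep2 = [i for i, sid in enumerate(current.individual_ids) if sid not in report.excluded_samples]
    if labels is not None:
        labels = [labels[i] for i in keep2]
    current = current.subset(sample_idx=keep2)

    pcs, outliers = pca_project(current, k=max(n_pcs, 2), outlier_sd=thresholds.pca_outlier_sd)
    for sid in outliers:
        report.exclude_sample(sid, "ancestry_outlier")
    keep3 = [i for i, sid in enumerate(current.individual_ids) if sid not in report.excluded_samples]
    if labels is not None:
        labels = [labels[i] for i in keep3]
    current = current.subset(sample_idx=keep3)

    variant_qc(current, thresholds, labels, report)
    vkeep = [j for j, v in enumerate(current.variants) if v.key not in report.excluded_variants]
    # duplicate exclusions are keyed with their column index; drop those columns too
    dup_cols = {int(k.split("#")[1]) for k in report.excluded_variants if "#" in k}
    vkeep = [j for j in vkeep if j not in dup_cols]
    current = current.subset(variant_idx=vkeep)
    current.refresh_metadata()

    pcs, _ = pca_project(current, k=max(n_pcs, 2), outlier_sd=thresholds.pca_outlier_sd)
    report.pcs = pcs
    report.summary_counts["kept_samples"] = current.n_individuals
    report.summary_counts["kept_variants"] = current.n_variants
    report.summary_counts["excluded_samples"] = len(report.excluded_samples)
    report.summary_counts["excluded_variants"] = len(report.excluded_variants)
    return current, report
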