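"""Clumping + thresholding (C+T) polygenic risk scores.

The score for individual *i* at p-value threshold *T* is the weighted sum
``PRS_i(T) = sum_j beta_j * g_ij`` over the LD-clumped discovery variants
with ``p_j < T``, where ``g_ij`` is the dosage of the effect allele and
``beta_j`` the discovery-GWAS effect size harmonized to the target
cohort's alt-allele convention.

Clumping is greedy on ascending p-value: each index SNP removes every
remaining SNP within a +/-250 kb window whose squared dosage correlation
(r^2, computed in the target cohort) exceeds 0.1.  The extended-LD MHC
region (chr6:27-33 Mb, hg19) is excluded before clumping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_THRESHOLDS = (5e-8, 1e-4, 0.001, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class SummaryStatRecord:
    """One discovery-GWAS variant: effect-allele beta (log-odds scale) and p-value."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    pvalue: float
    se: float = float("nan")
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


@dataclass
class ThresholdSet:
    """Ordered p-value cut-offs at which nested scores are computed."""

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds)
        if any(not 0.0 < x <= 1.0 for x in t):
            raise ValueError("thresholds must lie in (0, 1]")
        if any(a >= b for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = t


@dataclass
class ClumpParams:
    r2_max: float = 0.1
    window_kb: float = 250.0  # +/- window around the index SNP
    excluded_regions: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("6", 27_000_000, 33_000_000)]
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_max < 1.0:
            raise ValueError("r2_max must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class PrsResult:
    """Scores, clumped-SNP counts and cohort quartiles per threshold."""

    scores: pd.DataFrame  # individuals x thresholds
    n_snps: dict[float, int]
    quartiles: pd.DataFrame  # individuals x thresholds, labels Q1..Q4
    harmonization_counts: dict[str, int] = field(default_factory=dict)

    def series(self, threshold: float) -> pd.Series:
        return self.scores[threshold]


def harmonize(
    variants: pd.DataFrame,
    sumstats: list[SummaryStatRecord],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Match summary statistics to target variants and orient betas to the alt allele.

    ``variants`` must have columns chrom, pos, ref_allele, alt_allele and a
    ``var_idx`` column pointing into the genotype matrix.  Matching is by
    (chrom, pos): same alleles keep the beta, swapped alleles negate it,
    and strand-flipped records are complemented first.  Strand-ambiguous
    (A/T, C/G) pairs that would only match after a flip are dropped.
    """
    key = list(zip(variants["chrom"].astype(str), variants["pos"].astype(int)))
    if len(set(key)) != len(key):
        raise ValueError("duplicate (chrom, pos) in target variants; run variant QC first")
    index = {k: i for i, k in enumerate(key)}

    rows = []
    counts = {"matched": 0, "allele_swap": 0, "strand_flip": 0, "ambiguous_dropped": 0, "unmatched": 0, "mismatch_dropped": 0}
    for rec in sumstats:
        k = (str(rec.chrom), int(rec.pos))
        if k not in index:
            counts["unmatched"] += 1
            continue
        i = index[k]
        ref = str(variants["ref_allele"].iloc[i]).upper()
        alt = str(variants["alt_allele"].iloc[i]).upper()
        ea, oa = rec.effect_allele.upper(), rec.other_allele.upper()
        beta = None
        if (ea, oa) == (alt, ref):
            beta = rec.beta
        elif (ea, oa) == (ref, alt):
            beta = -rec.beta
            counts["allele_swap"] += 1
        else:
            cea = "".join(_COMPLEMENT.get(b, "N") for b in ea)
            coa = "".join(_COMPLEMENT.get(b, "N") for b in oa)
            if frozenset((ea, oa)) in (frozenset("AT"), frozenset("CG")):
                counts["ambiguous_dropped"] += 1
                continue
            if (cea, coa) == (alt, ref):
                beta = rec.beta
                counts["strand_flip"] += 1
            elif (cea, coa) == (ref, alt):
                beta = -rec.beta
                counts["strand_flip"] += 1
            else:
                counts["mismatch_dropped"] += 1
                continue
        counts["matched"] += 1
        rows.append(
            {
                "chrom": str(rec.chrom),
                "pos": int(rec.pos),
                "var_idx": int(variants["var_idx"].iloc[i]),
                "beta": float(beta),
                "pvalue": float(rec.pvalue),
            }
        )
    matched = pd.DataFrame(rows, columns=["chrom", "pos", "var_idx", "beta", "pvalue"])
    return matched, counts


def filter_target(
    variants: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    info_min: float = 0.4,
) -> pd.DataFrame:
    """Scoring-stage variant filter: MAF, call rate and imputation quality.

    All three comparisons are strict (a variant at exactly MAF 0.05 is
    excluded); absent info scores default to 1.0, the genotyped-variant
    convention.
    """
    info = variants["info_score"] if "info_score" in variants else pd.Series(1.0, index=variants.index)
    info = info.fillna(1.0)
    mask = (variants["maf"] > maf_min) & (variants["call_rate"] > call_rate_min) & (info > info_min)
    return variants.loc[mask]


def _in_region(chrom: str, pos: int, regions: list[tuple[str, int, int]]) -> bool:
    return any(str(c) == str(chrom) and lo <= pos <= hi for c, lo, hi in regions)


def clump(
    matched: pd.DataFrame,
    genotypes: GenotypeMatrix,
    params: ClumpParams | None = None,
) -> pd.DataFrame:
    """Greedy LD clumping of matched summary statistics.

    SNPs inside the excluded regions are removed up front.  The remainder
    is processed in ascending p-value order (ties by chrom, pos): the best
    remaining SNP becomes an index SNP and knocks out every remaining SNP
    on the same chromosome within the window whose target-cohort dosage
    r^2 with it exceeds ``r2_max``.  Index SNPs are returned in selection
    order.
    """
    params = params or ClumpParams()
    if matched.empty:
        return matched.copy()
    df = matched.loc[
        [not _in_region(c, p, params.excluded_regions) for c, p in zip(matched["chrom"], matched["pos"])]
    ].copy()
    if df.empty:
        return df
    df = df.sort_values(["pvalue", "chrom", "pos"], kind="mergesort").reset_index(drop=True)

    # mean-imputed dosage columns for the candidates, for r^2 on demand
    cols = df["var_idx"].to_numpy()
    X = genotypes.dosages[:, cols].astype(float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    X -= X.mean(axis=0)
    norms = np.sqrt((X**2).sum(axis=0))
    norms[norms == 0] = np.nan  # monomorphic: r^2 undefined, treated as 0

    window = params.window_kb * 1000.0
    alive = np.ones(len(df), dtype=bool)
    chroms = df["chrom"].to_numpy()
    positions = df["pos"].to_numpy()
    picked: list[int] = []
    for i in range(len(df)):
        if not alive[i]:
            continue
        picked.append(i)
        near = alive & (chroms == chroms[i]) & (np.abs(positions - positions[i]) <= window)
        near[i] = False
        idx = np.flatnonzero(near)
        if idx.size:
            with np.errstate(invalid="ignore"):
                r = (X[:, idx].T @ X[:, i]) / (norms[idx] * norms[i])
            r2 = np.nan_to_num(r) ** 2
            alive[idx[r2 > params.r2_max]] = False
        alive[i] = False
    return df.iloc[picked].reset_index(drop=True)


def select_by_threshold(clumped: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Index SNPs with p strictly below the threshold (nested across thresholds)."""
    return clumped.loc[clumped["pvalue"] < threshold]


def score(genotypes: GenotypeMatrix, snps: pd.DataFrame) -> pd.Series:
    """Weighted allele sum per individual.

    Missing dosages are replaced by the cohort mean (twice the alt-allele
    frequency), the standard PRS imputation for sporadic missingness.
    """
    if snps.empty:
        return pd.Series(0.0, index=genotypes.individual_ids)
    cols = snps["var_idx"].to_numpy()
    if (cols < 0).any() or (cols >= genotypes.n_variants).any():
        raise IndexError("SNP var_idx outside genotype matrix: harmonize against this matrix first")
    X = genotypes.dosages[:, cols].astype(float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    vals = X @ snps["beta"].to_numpy()
    return pd.Series(vals, index=genotypes.individual_ids)


def quartilize(scores: pd.Series) -> pd.Series:
    """Cohort quartile labels Q1..Q4 (Q4 = top quarter of the distribution).

    Boundaries are the 25/50/75 sample percentiles (linear interpolation);
    values tied with a boundary fall into the lower quartile.
    """
    if len(scores) < 4:
        raise ValueError("quartiles require at least 4 individuals")
    q25, q50, q75 = np.percentile(scores.to_numpy(), [25, 50, 75])
    if q25 == q75:
        warnings.warn("degenerate score distribution: quartile boundaries coincide", stacklevel=2)
    labels = np.where(
        scores <= q25, "Q1", np.where(scores <= q50, "Q2", np.where(scores <= q75, "Q3", "Q4"))
    )
    return pd.Series(labels, index=scores.index)


def build_prs(
    genotypes: GenotypeMatrix,
    sumstats: list[SummaryStatRecord],
    threshold_set: ThresholdSet | None = None,
    clump_params: ClumpParams | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    info_min: float = 0.4,
) -> PrsResult:
    """Full C+T chain: target filter -> harmonize -> clump -> score at each threshold."""
    threshold_set = threshold_set or ThresholdSet()
    vframe = pd.DataFrame(
        {
            "chrom": [v.chrom for v in genotypes.variants],
            "pos": [v.pos for v in genotypes.variants],
            "ref_allele": [v.ref_allele for v in genotypes.variants],
            "alt_allele": [v.alt_allele for v in genotypes.variants],
            "maf": [v.maf for v in genotypes.variants],
            "call_rate": [v.call_rate for v in genotypes.variants],
            "info_score": [v.info_score for v in genotypes.variants],
            "var_idx": np.arange(genotypes.n_variants),
        }
    )
    kept = filter_target(vframe, maf_min, call_rate_min, info_min)
    matched, counts = harmonize(kept, sumstats)
    clumped = clump(matched, genotypes, clump_params)

    scores = {}
    n_snps = {}
    quart = {}
    for t in threshold_set.thresholds:
        sel = select_by_threshold(clumped, t)
        s = score(genotypes, sel)
        scores[t] = s
        n_snps[t] = len(sel)
        quart[t] = quartilize(s) if len(s) >= 4 else pd.Series("Q1", index=s.index)
    logger.info("PRS built: %s", {f"{t:g}": n for t, n in n_snps.items()})
    return PrsResult(
        scores=pd.DataFrame(scores),
        n_snps=n_snps,
        quartiles=pd.DataFrame(quart),
        harmonization_counts=counts,
    )
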