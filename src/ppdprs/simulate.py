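"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a population-based ageing cohort genotyped on a
SNP array: biallelic variants in Hardy-Weinberg equilibrium with block
LD (Gaussian copula over haplotypes, AR(1) correlation within blocks), a
discovery GWAS whose effect estimates and p-values come from Wald
statistics at a configurable discovery sample size, and per-individual
MDS risk / prodromal marker profiles in which the probability of global
cognitive deficit is coupled to the true genetic liability through a
single loading parameter.

Defaults reproduce the structure of a community cohort of ~1,120
individuals aged 65+ (57.6% female) with a small genome-wide-significant
tier of SNPs and about 5% of individuals at >=30% prodromal-PD
probability.  Injectable QC failures (duplicate samples, relatives,
ancestry outliers, bad variants) come with a truth log so detection can
be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ppd import COGNITIVE_DOMAINS, MISSING, PRESENT, ABSENT, MarkerProfile
from .prs import SummaryStatRecord
from .qc import GenotypeMatrix, VariantInfo

RISK_MARKERS = (
    "male_sex",
    "pesticide_exposure",
    "caffeine_nonuse",
    "nonsmoking",
    "family_history_pd",
    "diabetes_type2",
    "physical_inactivity",
)

PRODROMAL_MARKERS = (
    "possible_rbd",
    "subthreshold_parkinsonism",
    "constipation",
    "daytime_somnolence",
    "orthostatic_hypotension",
    "erectile_dysfunction",
    "urinary_dysfunction",
    "depression_anxiety",
    "cognitive_deficit",
)

#: Baseline marker prevalences for a community-dwelling 65+ cohort.
#: cognitive_deficit is a cohort-quantile prevalence (see simulate_markers);
#: erectile_dysfunction applies to males only.
DEFAULT_PREVALENCES: dict[str, float] = {
    "pesticide_exposure": 0.15,
    "caffeine_nonuse": 0.12,
    "nonsmoking": 0.55,
    "family_history_pd": 0.04,
    "diabetes_type2": 0.15,
    "physical_inactivity": 0.25,
    "possible_rbd": 0.09,
    "subthreshold_parkinsonism": 0.13,
    "constipation": 0.13,
    "daytime_somnolence": 0.10,
    "orthostatic_hypotension": 0.07,
    "erectile_dysfunction": 0.30,
    "urinary_dysfunction": 0.22,
    "depression_anxiety": 0.18,
    "cognitive_deficit": 0.165,
}

_CHROMS = [str(c) for c in range(1, 23)]
#: chr6 starts just below the MHC so part of the chromosome falls in 27-33 Mb
_CHROM_START = {c: (26_500_000 if c == "6" else 1_000_000) for c in _CHROMS}
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    All randomness flows from ``seed`` through one generator; identical
    configs produce bit-identical cohorts.
    """

    n_individuals: int = 1120
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.35
    #: None -> 2.4% of variants (120 at the default 5,000)
    n_causal: int | None = None
    effect_sd: float = 0.05
    n_discovery: int = 450_000
    age_range: tuple[float, float] = (65.0, 90.0)
    prop_female: float = 0.576
    marker_prevalences: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    liability_loading: float = 0.3
    missing_rate: float = 0.005
    marker_missing_rate: float = 0.02
    #: global cognitive deficit is the bottom ``marker_prevalences['cognitive_deficit']``
    #: quantile of the composite z unless a fixed z threshold is given here
    deficit_z_threshold: float | None = None
    dementia_frac: float = 0.035
    mci_frac: float = 0.128
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_variants < 1:
            raise ValueError("cohort dimensions must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.n_causal is None:
            self.n_causal = max(1, round(0.024 * self.n_variants))
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        if self.n_discovery <= 0:
            raise ValueError("n_discovery must be positive")
        if self.age_range[0] < 50:
            raise ValueError("age_range must start at 50 or later (age-prior coverage)")
        for name, frac in [
            ("prop_female", self.prop_female),
            ("missing_rate", self.missing_rate),
            ("marker_missing_rate", self.marker_missing_rate),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, prev in self.marker_prevalences.items():
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"prevalence for {name!r} must be in [0, 1]")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    sumstats: list[SummaryStatRecord]
    profiles: list[MarkerProfile]
    true_scores: pd.Series  # oracle genetic liability, standardized
    truth_log: dict = field(default_factory=dict)
    batch_labels: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        ids = set(self.genotypes.individual_ids)
        if {p.individual_id for p in self.profiles} - ids:
            raise ValueError("profile ids not in genotype matrix")
        for key, entries in self.truth_log.items():
            for e in entries:
                ref_ids = e if isinstance(e, (list, tuple)) else [e]
                for r in ref_ids:
                    if isinstance(r, str) and r.startswith("ind") and r not in ids:
                        raise ValueError(f"truth_log {key} references unknown id {r}")


def _variant_positions(n_variants: int, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    per_chrom = int(np.ceil(n_variants / len(_CHROMS)))
    chroms: list[str] = []
    positions: list[int] = []
    for c in _CHROMS:
        k = min(per_chrom, n_variants - len(chroms))
        if k <= 0:
            break
        gaps = rng.integers(1000, 5001, size=k)
        pos = _CHROM_START[c] + np.cumsum(gaps)
        chroms.extend([c] * k)
        positions.extend(pos.tolist())
    return chroms, np.asarray(positions, dtype=int)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Dosages for a cohort of unrelated individuals with block LD.

    Haplotypes are generated from a Gaussian copula: within each block of
    ``ld_block_size`` consecutive variants the latent normals follow an
    AR(1) process with parameter ``ld_rho``; thresholding at the normal
    quantile of each variant's allele frequency yields Bernoulli alleles,
    so every variant is in HWE at its drawn frequency and blocks are
    mutually independent.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    chroms, positions = _variant_positions(m, rng)

    # two haplotypes per individual, AR(1) latent normals per block
    rho = config.ld_rho
    latents = np.empty((2 * n, m))
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        width = stop - start
        eps = rng.standard_normal((2 * n, width))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1.0 - rho**2) * eps[:, j]
        latents[:, start:stop] = z
    thresh = stats.norm.ppf(freqs)
    alleles = (latents < thresh).astype(float)
    dosages = alleles[0::2] + alleles[1::2]

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    ids = [f"ind{i:05d}" for i in range(n)]
    variants = []
    for j in range(m):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        variants.append(VariantInfo(chrom=chroms[j], pos=int(positions[j]), ref_allele=str(ref), alt_allele=str(alt)))
    matrix = GenotypeMatrix(ids, variants, dosages)
    matrix.refresh_metadata()
    return matrix


def true_genetic_scores(
    genotypes: GenotypeMatrix, causal_idx: np.ndarray, causal_betas: np.ndarray
) -> pd.Series:
    """Standardized oracle liability: centered causal dosages times true effects."""
    X = genotypes.dosages[:, causal_idx].astype(float)
    mean = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean, X)
    raw = (X - mean) @ causal_betas
    sd = raw.std(ddof=0)
    z = raw / sd if sd > 0 else raw
    return pd.Series(z, index=genotypes.individual_ids)


def simulate_summary_stats(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> tuple[list[SummaryStatRecord], np.ndarray, np.ndarray]:
    """Discovery-GWAS records: estimated betas with Wald p-values.

    ``n_causal`` variants drawn at random carry true effects
    ``N(0, effect_sd^2)``; every variant's estimate is true effect plus
    noise with the standard error ``1 / sqrt(2 N p (1-p))`` of a
    standardized continuous GWAS at discovery sample size ``N``.  Returns
    the records plus the causal indices and true betas (the oracle used by
    :func:`true_genetic_scores`).
    """
    if config.n_discovery <= 0:
        raise ValueError("n_discovery must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m = genotypes.n_variants
    freqs = np.array([v.maf for v in genotypes.variants])
    freqs = np.clip(freqs, 1e-4, 0.5)

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    true_beta = np.zeros(m)
    true_beta[causal_idx] = rng.normal(0.0, config.effect_sd, size=config.n_causal) if config.effect_sd > 0 else 0.0

    se = 1.0 / np.sqrt(2.0 * config.n_discovery * freqs * (1.0 - freqs))
    beta_hat = true_beta + rng.normal(0.0, se)
    zstat = beta_hat / se
    pvals = 2.0 * stats.norm.sf(np.abs(zstat))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    records = [
        SummaryStatRecord(
            chrom=v.chrom,
            pos=v.pos,
            effect_allele=v.alt_allele,
            other_allele=v.ref_allele,
            beta=float(beta_hat[j]),
            pvalue=float(pvals[j]),
            se=float(se[j]),
            maf=float(freqs[j]),
        )
        for j, v in enumerate(genotypes.variants)
    ]
    return records, causal_idx, true_beta[causal_idx]


def _state(flag: bool) -> str:
    return PRESENT if flag else ABSENT


def simulate_markers(
    config: SimulationConfig,
    true_scores: pd.Series,
    rng: np.random.Generator | None = None,
) -> list[MarkerProfile]:
    """MDS marker profiles coupled to the genetic liability.

    Binary markers are Bernoulli draws at their configured prevalence.
    Five cognitive-domain z-scores load negatively on the standardized
    true score with weight ``liability_loading``; global cognitive
    deficit, dementia and MCI are cut from the composite z (bottom
    cohort quantiles at the configured fractions), so deficit probability
    increases with liability.  Erectile dysfunction is assessed in males
    only and is missing for females; each other marker state is
    independently set to missing at ``marker_missing_rate``.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ids = list(true_scores.index)
    n = len(ids)
    z = np.asarray(true_scores, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("true scores must be finite")

    females = rng.random(n) < config.prop_female
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    prev = config.marker_prevalences

    # cognitive domains: z_d = -loading * liability + noise, standardized
    lam = config.liability_loading
    domain_z = {}
    for d in COGNITIVE_DOMAINS:
        raw = -lam * z + rng.standard_normal(n)
        domain_z[d] = raw / np.sqrt(lam**2 + 1.0)
    composite = np.mean(np.column_stack(list(domain_z.values())), axis=1)

    if config.deficit_z_threshold is not None:
        deficit = composite < config.deficit_z_threshold
    else:
        deficit = composite < np.quantile(composite, prev.get("cognitive_deficit", 0.165))
    dementia = composite < np.quantile(composite, config.dementia_frac)
    mci = ~dementia & (composite < np.quantile(composite, config.dementia_frac + config.mci_frac))

    draws = {
        name: rng.random(n) < prev.get(name, 0.0)
        for name in list(RISK_MARKERS) + list(PRODROMAL_MARKERS)
        if name not in ("male_sex", "cognitive_deficit")
    }
    miss = {
        name: rng.random(n) < config.marker_missing_rate
        for name in list(RISK_MARKERS) + list(PRODROMAL_MARKERS)
    }

    profiles = []
    for i, sid in enumerate(ids):
        risk = {}
        for name in RISK_MARKERS:
            if name == "male_sex":
                state = _state(not females[i])
            else:
                state = _state(draws[name][i])
            if miss[name][i]:
                state = MISSING
            risk[name] = state
        prod = {}
        for name in PRODROMAL_MARKERS:
            if name == "cognitive_deficit":
                state = _state(deficit[i])
            elif name == "erectile_dysfunction":
                state = MISSING if females[i] else _state(draws[name][i])
            else:
                state = _state(draws[name][i])
            if miss[name][i] and not (name == "erectile_dysfunction" and females[i]):
                state = MISSING
            prod[name] = state
        profiles.append(
            MarkerProfile(
                individual_id=sid,
                age=float(ages[i]),
                sex="female" if females[i] else "male",
                risk_markers=risk,
                prodromal_markers=prod,
                cognitive_z={d: float(domain_z[d][i]) for d in COGNITIVE_DOMAINS},
                dementia_flag=bool(dementia[i]),
                mci_flag=bool(mci[i]),
                pd_dlb_flag=False,
            )
        )
    return profiles


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: genotypes, discovery sumstats, marker profiles, oracle scores."""
    genotypes = simulate_genotypes(config)
    sumstats, causal_idx, causal_betas = simulate_summary_stats(config, genotypes)
    scores = true_genetic_scores(genotypes, causal_idx, causal_betas)
    profiles = simulate_markers(config, scores)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    batches = [f"center{rng.integers(1, config.n_batches + 1)}" for _ in range(config.n_individuals)]
    truth = {
        "causal_variants": [genotypes.variants[j].key for j in causal_idx],
    }
    return SyntheticCohort(
        genotypes=genotypes,
        sumstats=sumstats,
        profiles=profiles,
        true_scores=scores,
        truth_log=truth,
        batch_labels=batches,
        config=config,
    )


_FAILURE_KINDS = {
    "high_missingness_sample",
    "extreme_heterozygosity",
    "duplicate_sample",
    "relative_pair",
    "ancestry_outlier",
    "high_missingness_variant",
    "hwe_violation",
    "duplicate_variant",
    "ambiguous_variant",
}


def inject_qc_failures(
    cohort: SyntheticCohort, spec: Mapping[str, int], seed: int = 99
) -> SyntheticCohort:
    """Plant QC failures with clear margins and record them in the truth log.

    ``spec`` maps a failure kind to the number of injections.  Distinct
    samples/variants are used for each injection so reasons stay
    unambiguous; untouched entries are bit-identical to the input.
    """
    unknown = set(spec) - _FAILURE_KINDS
    if unknown:
        raise ValueError(f"unknown failure kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    geno = cohort.genotypes
    D = geno.dosages.copy()
    variants = [replace_variant(v) for v in geno.variants]
    n, m = D.shape
    truth = {k: list(v) for k, v in cohort.truth_log.items()}

    n_sample_slots = sum(
        spec.get(k, 0) * (2 if k in ("duplicate_sample", "relative_pair") else 1)
        for k in ("high_missingness_sample", "extreme_heterozygosity", "duplicate_sample", "relative_pair", "ancestry_outlier")
    )
    n_variant_slots = sum(
        spec.get(k, 0) * (2 if k == "duplicate_variant" else 1)
        for k in ("high_missingness_variant", "hwe_violation", "duplicate_variant", "ambiguous_variant")
    )
    sample_pool = list(rng.choice(n, size=n_sample_slots, replace=False)) if n_sample_slots else []
    variant_pool = list(rng.choice(m, size=n_variant_slots, replace=False)) if n_variant_slots else []

    def take_samples(k: int) -> list[int]:
        return [int(sample_pool.pop()) for _ in range(k)]

    def take_variants(k: int) -> list[int]:
        return [int(variant_pool.pop()) for _ in range(k)]

    for _ in range(spec.get("high_missingness_sample", 0)):
        (i,) = take_samples(1)
        mask = rng.random(m) < 0.10
        D[i, mask] = np.nan
        truth.setdefault("high_missingness_sample", []).append(geno.individual_ids[i])

    for _ in range(spec.get("extreme_heterozygosity", 0)):
        (i,) = take_samples(1)
        D[i, :] = 1.0
        truth.setdefault("extreme_heterozygosity", []).append(geno.individual_ids[i])

    for _ in range(spec.get("duplicate_sample", 0)):
        i, j = take_samples(2)
        src = D[i, :].copy()
        flips = rng.random(m) < 0.01
        src[flips] = np.where(src[flips] >= 1.0, src[flips] - 1.0, src[flips] + 1.0)
        D[j, :] = src
        truth.setdefault("duplicate_sample", []).append([geno.individual_ids[i], geno.individual_ids[j]])

    for _ in range(spec.get("relative_pair", 0)):
        i, j = take_samples(2)
        share = rng.random(m) < 0.5  # first-degree-like sharing
        D[j, share] = D[i, share]
        truth.setdefault("relative_pair", []).append([geno.individual_ids[i], geno.individual_ids[j]])

    for _ in range(spec.get("ancestry_outlier", 0)):
        (i,) = take_samples(1)
        # Strongly shifted allele-frequency profile, but heterozygosity-balanced:
        # per variant choose an up-shift (towards 0.5-0.95) or a down-shift
        # (towards 0.02), greedily keeping the expected het rate at the cohort's,
        # so the sample is an ancestry outlier without tripping the het filter.
        p = np.array([np.nanmean(D[:, j]) / 2.0 for j in range(m)])
        p = np.clip(p, 0.02, 0.98)
        p_up = np.clip(p + 0.45, 0.02, 0.95)
        p_down = np.full(m, 0.02)
        h0 = 2 * p * (1 - p)
        h_up = 2 * p_up * (1 - p_up)
        h_down = 2 * p_down * (1 - p_down)
        shifted = np.empty(m)
        deficit = 0.0
        for j in rng.permutation(m):
            d_up = deficit + (h_up[j] - h0[j])
            d_down = deficit + (h_down[j] - h0[j])
            if abs(d_up) <= abs(d_down):
                shifted[j], deficit = p_up[j], d_up
            else:
                shifted[j], deficit = p_down[j], d_down
        D[i, :] = rng.binomial(2, shifted).astype(float)
        truth.setdefault("ancestry_outlier", []).append(geno.individual_ids[i])

    for _ in range(spec.get("high_missingness_variant", 0)):
        (j,) = take_variants(1)
        mask = rng.random(n) < 0.10
        D[mask, j] = np.nan
        truth.setdefault("high_missingness_variant", []).append(variants[j].key)

    for _ in range(spec.get("hwe_violation", 0)):
        (j,) = take_variants(1)
        D[:, j] = 1.0
        truth.setdefault("hwe_violation", []).append(variants[j].key)

    for _ in range(spec.get("duplicate_variant", 0)):
        j, k = take_variants(2)
        # the source must not itself violate another rule (ambiguous at high
        # MAF), or the pair would be excluded for a different reason
        if variants[j].is_ambiguous and variants[j].maf > 0.35:
            for idx, cand in enumerate(variant_pool):
                if not (variants[cand].is_ambiguous and variants[cand].maf > 0.35):
                    variant_pool[idx] = j
                    j = int(cand)
                    break
        variants[k] = VariantInfo(
            chrom=variants[j].chrom,
            pos=variants[j].pos,
            ref_allele=variants[j].ref_allele,
            alt_allele=variants[j].alt_allele,
            info_score=variants[j].info_score,
        )
        D[:, k] = D[:, j]
        # the copy gets slightly more missingness, so dedup keeps the original;
        # kept well below the per-batch missingness bound
        extra = rng.choice(n, size=max(1, n // 100), replace=False)
        D[extra, k] = np.nan
        truth.setdefault("duplicate_variant", []).append(variants[k].key)

    for _ in range(spec.get("ambiguous_variant", 0)):
        (j,) = take_variants(1)
        pair = ("A", "T") if rng.random() < 0.5 else ("C", "G")
        variants[j] = VariantInfo(chrom=variants[j].chrom, pos=variants[j].pos, ref_allele=pair[0], alt_allele=pair[1])
        D[:, j] = rng.binomial(2, 0.5, size=n).astype(float)  # MAF ~0.5 > 0.4 bound
        truth.setdefault("ambiguous_variant", []).append(variants[j].key)

    new_geno = GenotypeMatrix(list(geno.individual_ids), variants, D)
    new_geno.refresh_metadata()
    return SyntheticCohort(
        genotypes=new_geno,
        sumstats=list(cohort.sumstats),
        profiles=list(cohort.profiles),
        true_scores=cohort.true_scores.copy(),
        truth_log=truth,
        batch_labels=list(cohort.batch_labels),
        config=cohort.config,
    )


def replace_variant(v: VariantInfo) -> VariantInfo:
    return VariantInfo(
        chrom=v.chrom,
        pos=v.pos,
        ref_allele=v.ref_allele,
        alt_allele=v.alt_allele,
        maf=v.maf,
        call_rate=v.call_rate,
        info_score=v.info_score,
        build=v.build,
    )
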