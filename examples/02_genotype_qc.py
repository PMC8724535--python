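"""Inject genotype-level failures and verify that QC catches each of them.

Runs the full sample + variant QC chain (missingness, heterozygosity,
kinship pruning at pi-hat 0.125, PCA ancestry outliers, per-batch and
differential missingness, HWE, strand-ambiguity, duplicate variants) on a
cohort with one planted failure of each kind.
"""

from collections import Counter

from ppdprs import SimulationConfig, inject_qc_failures, run_qc, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_individuals=400, n_variants=2000, seed=5))
cohort = inject_qc_failures(
    cohort,
    {
        "high_missingness_sample": 1,
        "duplicate_sample": 1,
        "ancestry_outlier": 1,
        "hwe_violation": 1,
        "ambiguous_variant": 1,
    },
    seed=9,
)

clean, report = run_qc(cohort.genotypes, batch_labels=cohort.batch_labels)

print(f"kept {clean.n_individuals}/{cohort.genotypes.n_individuals} samples, "
      f"{clean.n_variants}/{cohort.genotypes.n_variants} variants")
print("sample exclusion reasons:", dict(Counter(report.excluded_samples.values())))
print("variant exclusion reasons:", dict(Counter(report.excluded_variants.values())))
for kind, entries in cohort.truth_log.items():
    if kind == "causal_variants":
        continue
    print(f"  injected {kind}: {entries}")

# Every injected id should appear in the exclusion maps with the matching
# reason; ambiguous variants at MAF > 0.4 also occur naturally and are
# removed by the same rule.
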