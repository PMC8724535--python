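"""Build clumping+thresholding polygenic risk scores and check recovery.

PRS_i(T) = sum of effect-allele dosages weighted by discovery betas over
LD-clumped SNPs with p < T (r^2 > 0.1 removed within +/-250 kb windows,
MHC excluded).  With the generator's oracle liability available we can
measure how well each threshold recovers the truth.
"""

import numpy as np

from ppdprs import SimulationConfig, ThresholdSet, build_prs, run_qc, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_individuals=800, n_variants=3000, seed=17))
clean, _ = run_qc(cohort.genotypes, batch_labels=cohort.batch_labels)

result = build_prs(clean, cohort.sumstats, ThresholdSet((5e-8, 1e-4, 0.05, 0.5)))

print("threshold  n_snps  corr(PRS, true liability)")
for t in result.scores.columns:
    s = result.scores[t]
    r = np.corrcoef(s, cohort.true_scores[s.index])[0, 1]
    print(f"{t:<10g} {result.n_snps[t]:<7d} {r:.3f}")
print("harmonization:", result.harmonization_counts)

# The strictest threshold keeps only the genome-wide-significant tier and
# typically recovers the liability best: looser thresholds add mostly
# null SNPs, diluting the signal.
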