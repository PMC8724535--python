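"""Generate a synthetic ageing cohort and look at its structure.

The generator emulates a community-dwelling 65+ cohort: array genotypes in
HWE with block LD, a discovery GWAS with a genome-wide-significant tier,
and MDS risk/prodromal marker profiles whose cognitive component is
coupled to the true genetic liability.
"""

import numpy as np

from ppdprs import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_individuals=600, n_variants=2000, seed=42))

g = cohort.genotypes
pvals = np.array([s.pvalue for s in cohort.sumstats])
females = sum(p.sex == "female" for p in cohort.profiles)

print(f"cohort: {g.n_individuals} individuals x {g.n_variants} variants")
print(f"female: {females / g.n_individuals:.1%}")
print(f"mean MAF: {np.mean([v.maf for v in g.variants]):.3f}")
print(f"genome-wide significant discovery SNPs (p < 5e-8): {(pvals < 5e-8).sum()}")
print(f"oracle liability: mean {cohort.true_scores.mean():.3f}, sd {cohort.true_scores.std():.3f}")

# The GWS count is the tier the PRS at the strictest threshold is built
# from; the liability is the standardized truth the PRS should recover.
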