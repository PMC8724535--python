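"""Compute the MDS probability of prodromal PD for a hand-built profile.

The calculator turns an age-band pretest probability into posttest
probability by multiplying the likelihood ratios of every assessed risk
and prodromal marker on the odds scale; missing markers contribute 1.0.
"""

from ppdprs import LikelihoodRatioTable, MarkerProfile, compute_ppd
from ppdprs.ppd import ABSENT, MISSING, PRESENT

table = LikelihoodRatioTable.default()

profile = MarkerProfile(
    individual_id="demo",
    age=72.0,
    sex="male",
    risk_markers={
        "male_sex": PRESENT,
        "pesticide_exposure": ABSENT,
        "caffeine_nonuse": ABSENT,
        "nonsmoking": PRESENT,
        "family_history_pd": PRESENT,
        "diabetes_type2": MISSING,
        "physical_inactivity": ABSENT,
    },
    prodromal_markers={
        "possible_rbd": PRESENT,
        "subthreshold_parkinsonism": ABSENT,
        "constipation": PRESENT,
        "daytime_somnolence": ABSENT,
        "urinary_dysfunction": ABSENT,
        "depression_anxiety": ABSENT,
        "cognitive_deficit": ABSENT,
    },
)

res = compute_ppd(profile, table)
print(f"pretest probability (age {profile.age:.0f}): {res.pretest_prob:.3f}")
print(f"total risk LR      : {res.risk_lr:.3f}")
print(f"total prodromal LR : {res.prodromal_lr:.3f}")
print(f"total LR           : {res.total_lr:.3f}")
print(f"posttest probability: {res.posttest_prob:.3f}")
print(f">=30% / >=50% / >=80%: {res.ge_30} / {res.ge_50} / {res.ge_80}")

# A 72-year-old starts at 2.5% pretest probability; a positive family
# history, possible RBD and constipation push the odds up, while the
# absent markers pull them below 1, yielding the posttest probability.
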