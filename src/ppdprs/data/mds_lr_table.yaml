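# Likelihood-ratio table for the MDS research criteria for prodromal
# Parkinson's disease (2019 update of the criteria).
#
# Values are editable: swap this file (or pass --lr-table) to use a
# different criteria revision without code changes.  Every pipeline run
# logs the SHA-256 of the table actually used.
#
# lr_positive is applied when a marker is present, lr_negative when it is
# documented absent; markers in state "missing" always contribute 1.0.

version: "mds-2019"

# Pretest probability of prodromal PD by age band (half-open [lo, hi)).
# The last band is open-ended.
age_priors:
  - {lo: 50, hi: 55, prior: 0.004}
  - {lo: 55, hi: 60, prior: 0.0075}
  - {lo: 60, hi: 65, prior: 0.0125}
  - {lo: 65, hi: 70, prior: 0.02}
  - {lo: 70, hi: 75, prior: 0.025}
  - {lo: 75, hi: 80, prior: 0.035}
  - {lo: 80, hi: .inf, prior: 0.04}

risk_markers:
  male_sex:                 {lr_positive: 1.2,  lr_negative: 0.8}
  pesticide_exposure:       {lr_positive: 1.5,  lr_negative: 1.0}
  solvent_exposure:         {lr_positive: 1.5,  lr_negative: 1.0}
  caffeine_nonuse:          {lr_positive: 1.35, lr_negative: 0.88}
  nonsmoking:               {lr_positive: 1.2,  lr_negative: 0.8}
  family_history_pd:        {lr_positive: 2.5,  lr_negative: 1.0}
  diabetes_type2:           {lr_positive: 1.5,  lr_negative: 1.0}
  physical_inactivity:      {lr_positive: 1.3,  lr_negative: 0.8}

prodromal_markers:
  possible_rbd:             {lr_positive: 2.8,  lr_negative: 0.89}
  subthreshold_parkinsonism: {lr_positive: 10.0, lr_negative: 0.7}
  olfactory_loss:           {lr_positive: 6.4,  lr_negative: 0.4}
  constipation:             {lr_positive: 2.5,  lr_negative: 0.82}
  daytime_somnolence:       {lr_positive: 2.7,  lr_negative: 0.86}
  orthostatic_hypotension:  {lr_positive: 3.2,  lr_negative: 0.8}
  erectile_dysfunction:     {lr_positive: 3.4,  lr_negative: 0.87}
  urinary_dysfunction:      {lr_positive: 1.9,  lr_negative: 0.9}
  depression_anxiety:       {lr_positive: 1.6,  lr_negative: 0.88}
  cognitive_deficit:        {lr_positive: 1.8,  lr_negative: 0.88}

# LR scheme used when the cohort PRS quartile stands in as a genetic risk
# marker: top quartile raises the odds, bottom quartile lowers them, the
# middle half is neutral.
prs_quartile_scheme:
  Q1: 0.45
  Q2: 1.0
  Q3: 1.0
  Q4: 1.57
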