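# Conjunctive (AND) rating experiment: 999 subjects x 5 trials, 1-9 scale.
# Slopes are scaled-rating change per 0.1 probability step; calibrated to
# the reported abnormal-inflation (-0.02) and supersession (+0.03) effects.
# Jumps move the certain (p = 1) conditions off the linear extrapolation by
# the reported displacements; suppression 0 removes each prior's effect
# when the other prior is certain.
structure: conjunctive
n_subjects: 999
trials_per_subject: 5
intercept: 0.45
slope_focal: -0.02
slope_alternate: 0.03
jump_focal_certain: -0.15
jump_alternate_certain: 0.16
suppress_focal_when_alt_certain: 0.0
suppress_alt_when_focal_certain: 0.0
sd_intercept: 0.1
sd_slope_focal: 0.02
sd_slope_alternate: 0.02
sd_residual: 0.2
seed: 0
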