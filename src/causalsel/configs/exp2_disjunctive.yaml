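# Disjunctive (OR) rating experiment: 1013 subjects x 5 trials, 1-9 scale.
# Calibrated to the reported abnormal-deflation (+0.01) and reverse-
# supersession (-0.005) effects; the only certainty jump sits at the
# alternate-certain conditions (no focal-certain jump was observed).
structure: disjunctive
n_subjects: 1013
trials_per_subject: 5
intercept: 0.52
slope_focal: 0.01
slope_alternate: -0.005
jump_focal_certain: 0.0
jump_alternate_certain: -0.045
suppress_focal_when_alt_certain: 0.0
suppress_alt_when_focal_certain: 0.0
sd_intercept: 0.1
sd_slope_focal: 0.02
sd_slope_alternate: 0.02
sd_residual: 0.2
seed: 0
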