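# No planted age effects anywhere; used for type-I error checks.
n_samples: 400
gi_slope: 0.0
loh_ratio_slope: 0.0
wgd_logit_slope: 0.0
burden_log_slope: 0.0
ct_fraction_slope: 0.0
hypermutator_rate_young: 0.0
hypermutator_rate_old: 0.0
driver_or_per_year: 1.0
meth_age_slope: 0.0
coupling: 0.0
arm_gain_or_per_year: 1.0
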