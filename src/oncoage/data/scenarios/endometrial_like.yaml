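# Rising instability/WGD/burden with age, age-increasing C>T share,
# young-enriched hypermutators, negative methylation->expression coupling.
n_samples: 400
gi_slope: 0.003
loh_ratio_slope: 0.002
wgd_logit_slope: 0.03
burden_log_slope: 0.01
ct_fraction_slope: 0.004
hypermutator_rate_young: 0.34
hypermutator_rate_old: 0.11
driver_or_per_year: 1.0
meth_age_slope: 0.003
coupling: -4.0
arm_gain_or_per_year: 1.03
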