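# Age-decreasing driver mutation odds (IDH1-like), mild instability trend,
# no hypermutator subpopulation.
n_samples: 400
gi_slope: 0.002
loh_ratio_slope: 0.001
wgd_logit_slope: 0.01
burden_log_slope: 0.008
ct_fraction_slope: 0.003
hypermutator_rate_young: 0.0
hypermutator_rate_old: 0.0
driver_or_per_year: 0.96
meth_age_slope: 0.002
coupling: -3.0
arm_gain_or_per_year: 1.02
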