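sex	age_lo	age_hi	slope	intercept
male	18	30	0.063	2.896
male	30	60	0.048	3.653
male	60	200	0.049	2.459
female	18	30	0.062	2.036
female	30	60	0.034	3.538
female	60	200	0.038	2.755
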