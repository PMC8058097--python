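chromosome	length	cen_start	cen_end	acrocentric
1	1000000	450001	550000	0
2	800000	350001	450000	0
3	600000	1	100000	1
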