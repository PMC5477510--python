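mirna	fold_change	adjusted_p
miR-146a-5p	0.49	1.860E-05
miR-425-3p	0.50	1.415E-04
miR-24-3p	0.76	3.255E-04
miR-146b-5p	0.79	0.004
miR-503-5p	0.48	0.007
miR-3074-5p	0.73	0.007
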