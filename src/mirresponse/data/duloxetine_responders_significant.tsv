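mirna	fold_change	adjusted_p
miR-425-3p	0.46	2.639E-08
miR-24-3p	0.70	6.813E-06
miR-503-5p	0.45	6.987E-06
miR-146a-5p	0.60	3.748E-05
miR-215-5p	1.50	8.744E-05
miR-3074-5p	0.76	1.616E-04
miR-1180-3p	0.75	2.487E-04
miR-425-5p	0.86	0.001
miR-324-5p	0.78	0.001
miR-146b-5p	0.66	0.001
miR-6750-3p	1.27	0.005
miR-6511a-3p	1.21	0.007
miR-361-5p	0.84	0.009
miR-3173-5p	1.30	0.023
miR-2110	0.81	0.026
miR-3605-3p	1.17	0.032
miR-6881-3p	1.27	0.032
miR-30e-5p	1.19	0.035
miR-423-3p	1.12	0.035
miR-361-3p	1.10	0.040
miR-3184-5p	1.12	0.050
hsa-miR-636	1.14	0.050
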