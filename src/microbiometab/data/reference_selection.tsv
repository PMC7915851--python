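metabolite	hmdb	flag_3class	flag_2class	flag_anova	dir_ANR	dir_ANBP	vip_3class	vip_2class	anova_p
acetic_acid	HMDB0000042	0	1	0	down	up	0.82	2.10	0.31
allose	HMDB0001151	0	0	1	down	up	0.71	0.93	0.012
alpha_ketoisovaleric_acid	HMDB0000019	1	0	0	down	up	2.35	0.88	0.22
arabinose	HMDB0029942	1	1	0	down	down-down	1.92	1.77	0.09
deoxyadenosine	HMDB0000101	0	1	0	down	down-down	0.64	2.31	0.18
deoxycytidine	HMDB0000014	1	0	1	down	down-down	2.52	1.12	0.004
glycerol	HMDB0000131	1	0	1	down	up	1.68	0.55	0.021
homogentistic_acid	HMDB0000130	0	0	1	down	up	1.02	0.79	0.033
isoleucine	HMDB0000172	1	0	1	down	down-down	1.77	0.92	0.008
lactose	HMDB0000186	0	1	0	down	up	0.58	1.95	0.41
leucine	HMDB0000687	1	0	0	down	down-down	1.66	1.08	0.07
malic_acid	HMDB0000156	0	0	1	down	down-down	1.21	0.86	0.019
n_acetyl_glucosamine	HMDB0000803	1	0	1	down-down	down	1.61	0.73	0.027
palmitic_acid	HMDB0000220	0	0	1	down-down	down	0.95	0.61	0.038
p_hydroxyphenylacetic_acid	HMDB0000020	1	0	1	down	up	2.08	1.31	0.015
pyroglutamic_acid	HMDB0000267	0	1	0	down	down-down	0.88	1.82	0.26
rhamnose	HMDB0000849	1	1	1	down	down-down	2.74	2.58	0.001
scyllo_inositol	HMDB0006088	0	1	0	down	up	0.47	1.71	0.35
sebacic_acid	HMDB0000792	0	1	0	down	up	0.69	1.64	0.44
sorbose	HMDB0001266	0	0	1	down-down	down	1.35	1.18	0.009
succinic_acid	HMDB0000254	0	1	1	down	up	1.11	1.89	0.024
tagatose	HMDB0003418	1	0	1	down-down	down	2.22	1.04	0.006
threonic_acid	HMDB0000943	0	1	0	down	up	0.76	2.04	0.29
threonine	HMDB0000167	0	0	1	down	up	0.91	1.26	0.042
tyrosine	HMDB0000158	1	0	0	down	up	2.61	0.67	0.11
valine	HMDB0000883	1	0	0	down	down-down	1.88	1.15	0.06
xylose	HMDB0000098	1	1	1	down	down-down	2.43	2.19	0.002
gamma_aminobutyric_acid	HMDB0000112	0	1	0	down	down	0.53	1.58	0.37
unselected_1	HMDB0099901	0	0	0	down	up	0.92	0.81	0.48
unselected_2	HMDB0099902	0	0	0	up	up	1.24	0.66	0.19
unselected_3	HMDB0099903	0	0	0	down	down	1.49	1.50	0.06
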