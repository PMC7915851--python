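variable	n_ANR	mean_ANR	sd_ANR	n_ANBP	mean_ANBP	sd_ANBP	n_CTRL	mean_CTRL	sd_CTRL	f_printed	p_printed
age_years	17	20.5	3.1	6	25.2	5.2	20	23.0	3.3	4.94	0.02
body_weight_kg	17	38.6	6.0	6	39.8	4.3	20	55.2	6.3	39.59	3.29e-10
bmi	17	15.0	1.8	6	14.7	1.5	20	20.3	1.4	59.29	1.08e-12
ede_restraint	17	4.5	0.9	6	4.4	1.2	20	0.2	0.6	146.07	4.12e-19
ede_eating_concern	17	3.7	1.1	6	3.8	1.3	20	0.1	0.4	91.61	1.17e-15
ede_weight_concern	17	4.2	1.5	6	3.7	0.8	20	0.3	0.7	63.55	3.82e-13
ede_shape_concern	17	4.8	1.3	6	4.7	1.5	20	0.5	1.0	66.19	2.05e-13
bsi_somatization	17	1.8	0.9	6	2.5	1.1	20	0.1	0.2	36.45	9.69e-10
bsi_obsessive_compulsive	17	2.2	0.2	6	3.0	0.3	20	0.3	0.4	43.26	9.96e-11
bsi_interpersonal_sensitivity	17	2.7	0.8	6	3.3	0.8	20	0.1	0.2	116.57	2.05e-17
bsi_depression	17	2.7	0.7	6	3.2	0.5	20	0.2	0.2	145.62	4.34e-19
bsi_anxiety	17	2.6	0.8	6	3.3	0.5	20	0.4	0.2	93.17	8.83e-16
bsi_hostility	17	1.6	0.8	6	2.4	1.2	20	0.2	0.3	27.80	2.69e-8
bsi_phobic_anxiety	17	1.5	1.0	6	1.9	0.9	20	0.1	0.1	24.78	9.94e-8
bsi_paranoid_ideation	17	1.8	0.9	6	2.3	0.8	20	0.1	0.3	36.55	9.37e-10
bsi_psychoticism	17	2.1	0.8	6	2.6	0.9	20	0.1	0.2	64.62	2.95e-13
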