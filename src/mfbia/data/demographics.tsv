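gender	decade	age_mean	age_sd	weight_mean	weight_sd	height_mean	height_sd	bmi_mean	bmi_sd
men	20	28	1	90	1	1.86	0.07	26.0	1.7
men	30	35	3	90	11	1.85	0.04	26.0	2.8
men	40	44	5	90	8	1.83	0.01	26.8	2.2
men	50	53	3	83	19	1.81	0.10	25.5	3.2
men	60	65	3	72	8	1.76	0.03	23.3	2.7
women	20	25	4	64	1	1.71	0.06	21.8	1.1
women	30	35	5	63	6	1.69	0.07	22.0	4.3
women	40	44	3	62	1	1.65	0.06	22.7	2.0
women	50	54	2	67	11	1.69	0.04	23.4	4.1
women	60	62	2	69	18	1.65	0.03	25.4	5.4
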