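subject	csp_lda	csp_bagging	regcsp	pooling	l1_mtl	l21_mtl	within_subject_csp
2	57.50	50.00	51.25	50.00	50.00	50.00	71.3
4	58.75	62.50	57.50	50.00	55.00	56.25	73.8
6	50.00	55.00	50.00	50.00	46.25	42.50	71.1
7	50.00	48.75	43.75	50.00	66.25	51.25	55.0
8	60.00	60.00	53.75	52.50	57.50	58.75	97.5
9	77.50	85.00	50.00	50.00	51.25	48.75	81.3
10	61.25	58.75	62.50	50.00	53.75	46.25	66.3
13	50.00	50.00	58.75	50.00	51.25	46.25	56.3
15	52.50	51.25	52.50	50.00	53.75	52.50	63.2
16	51.25	56.25	47.50	50.00	60.00	57.50	50.0
17	56.25	50.00	58.75	50.00	56.25	65.00	61.3
18	48.75	50.00	56.25	48.75	63.75	57.50	59.3
3	52.50	56.25	55.00	50.00	55.00	53.75	65.0
5	53.75	50.00	52.50	50.00	45.00	56.25	58.8
11	56.25	51.25	53.75	50.00	47.50	45.00	67.5
12	48.75	50.00	47.50	50.00	48.75	50.00	53.8
14	50.00	61.25	66.25	50.00	46.25	45.00	83.8
mean	55.25	55.66	53.97	50.07	53.38	51.91	66.76
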