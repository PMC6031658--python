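subject	csp_lda	csp_bagging	regcsp	pooling	l1_mtl	l21_mtl	within_subject_l1
2	51.25	52.50	60.00	68.75	66.25	72.50	65.00
4	52.50	50.00	55.00	57.50	62.50	61.25	72.50
6	47.50	42.50	50.00	37.50	55.00	45.00	62.50
7	58.75	57.50	50.00	82.50	73.75	93.75	88.75
8	78.75	67.50	61.25	57.50	58.75	62.50	73.75
9	71.25	80.00	75.00	68.75	66.25	71.25	65.00
10	70.00	68.75	52.50	67.50	71.25	73.75	56.25
13	55.00	58.75	56.25	77.50	65.00	76.25	80.00
15	56.25	62.50	53.75	81.25	72.50	86.25	85.00
16	52.50	53.75	53.75	66.25	71.25	72.50	67.50
17	51.25	50.00	53.75	57.50	53.75	65.00	73.75
18	66.25	58.75	60.00	80.00	86.25	86.25	83.75
3	67.50	60.00	53.75	42.50	46.25	50.00	56.25
5	58.75	56.25	56.25	62.50	65.00	57.50	70.00
11	60.00	57.50	50.00	70.00	67.50	61.25	51.25
12	50.00	50.00	50.00	46.25	51.25	51.25	65.00
14	81.25	85.00	70.00	62.50	67.50	63.75	62.50
mean	60.51	59.49	56.54	63.90	64.71	67.65	69.34
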