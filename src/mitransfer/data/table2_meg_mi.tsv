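subject	csp_lda	csp_bagging	regcsp	pooling	l1_mtl	l21_mtl	within_subject_l1
1	61.25	62.50	58.75	77.50	77.50	78.75	86.25
2	86.25	76.25	67.50	77.50	81.25	81.25	88.75
4	82.50	77.50	71.25	70.00	63.75	63.75	71.25
6	68.75	67.50	52.50	63.75	66.25	68.75	85.00
7	56.25	53.75	58.75	67.50	75.00	83.75	82.50
8	71.25	56.25	58.75	67.50	62.50	61.25	58.75
9	70.00	67.50	65.00	68.75	70.00	71.25	86.25
10	50.00	50.00	50.00	65.00	65.00	61.25	63.75
13	65.00	62.50	55.00	65.00	70.00	70.00	95.00
15	68.75	67.50	65.00	86.25	93.75	96.25	95.00
16	51.25	55.00	60.00	73.75	72.50	76.25	77.50
17	57.50	62.50	53.75	73.75	73.75	76.25	86.25
18	58.75	48.75	56.25	71.25	76.25	81.25	91.25
3	52.50	55.00	55.00	58.75	53.75	56.25	48.75
5	57.50	58.75	56.25	65.00	53.75	46.25	60.00
11	51.25	51.25	53.75	75.00	70.00	70.00	66.25
12	52.50	50.00	51.25	52.50	62.50	60.00	53.75
14	66.25	71.25	61.25	68.75	60.00	67.50	53.75
mean	62.64	60.76	58.33	69.31	69.31	70.56	75.00
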