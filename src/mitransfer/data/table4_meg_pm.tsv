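subject	csp_lda	csp_bagging	regcsp	pooling	l1_mtl	l21_mtl	online_csp
1	61.25	68.75	57.50	63.75	57.50	65.00	71.30
2	81.25	72.50	63.75	46.25	58.75	56.25	77.50
4	78.75	87.50	50.00	53.75	50.00	51.25	75.00
6	58.75	51.25	61.25	55.00	56.25	53.75	67.50
7	52.50	50.00	56.25	58.75	56.25	57.50	62.50
8	57.50	50.00	76.25	63.75	57.50	63.75	85.00
9	62.50	66.25	62.50	53.75	53.75	52.50	68.80
10	60.00	50.00	61.25	56.25	57.50	61.25	63.80
13	52.50	53.75	56.25	47.50	48.75	46.25	57.50
15	43.75	48.75	50.00	66.25	60.00	65.00	53.80
16	51.25	50.00	51.25	47.50	46.25	40.00	51.30
17	56.25	53.75	57.50	63.75	63.75	60.00	56.30
18	50.00	50.00	56.25	63.75	56.25	57.50	55.00
3	51.25	50.00	48.75	51.25	52.50	46.25	47.50
5	58.75	56.25	50.00	58.75	53.75	53.75	52.50
11	51.25	57.50	53.75	61.25	47.50	41.25	60.00
12	52.50	65.00	50.00	50.00	36.25	40.00	66.30
14	56.25	50.00	52.50	56.25	51.25	53.75	58.80
mean	57.57	57.29	56.39	56.53	53.54	53.61	62.80
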