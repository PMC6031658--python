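subject	within_subject_l1	online_decoding	average
1	86.25	71.30	78.78
2	88.75	77.50	83.13
4	71.25	75.00	73.13
6	85.00	67.50	76.25
7	82.50	62.50	72.50
8	58.75	85.00	71.88
9	86.25	68.80	77.53
10	63.75	63.80	63.78
13	95.00	57.50	76.25
15	95.00	53.80	74.40
16	77.50	51.30	64.40
17	86.25	56.30	71.28
18	91.25	55.00	73.13
3	48.75	47.50	48.13
5	60.00	52.50	56.25
11	66.25	60.00	63.13
12	53.75	66.30	60.03
14	53.75	58.80	56.28
mean	75.00	62.80	68.90
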