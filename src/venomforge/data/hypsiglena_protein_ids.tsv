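protein	score	peptide_matches	pct_coverage	group
CRISP-1b	90678.90	28	97.29	1
CRISP-1d	90678.90	28	97.29	1
CRISP-1a	83532.05	29	97.29	2
CRISP-1c	83532.05	29	97.29	2
CRISP-1e	80437.63	27	92.56	2
CTL-7e	36677.55	17	96.24	3
CTL-7d	36677.55	14	63.91	3
CTL-7b	36677.55	17	96.24	3
CTL-7a	36677.55	17	96.24	3
CTL-7c	36564.01	15	84.96	3
CTL-8g	26033.11	19	82.22	4
CTL-8f	25919.58	18	81.62	4
CTL-8e	25919.58	18	82.22	4
CTL-8d	25919.58	18	81.62	4
CTL-8c	25919.58	18	81.62	4
CTL-8b	25919.58	18	81.62	4
CTL-8a	25919.58	18	81.62	4
Fused	3986.49	9	53.45	5
SVMPIII-1	2196.46	23	41.14	6
SVMPIII-3a	6757.38	33	44.41	7
SVMPIII-3b	6757.38	34	44.41	7
SVMPIII-3c	6754.13	33	44.41	7
SVMPIII-3d	6754.65	32	44.41	7
SVMPIII-4	22516.59	42	59.05	8
SVMPIII-5	5473.71	36	43.56	9
SVMPIII-6a	4589.49	27	39.20	10
SVMPIII-6b	4596.38	29	39.20	10
SVMPIII-6c	4589.49	27	39.20	10
SVMPIII-7a	10796.01	28	61.87	11
SVMPIII-7b	10792.75	27	61.87	11
SVMPIII-8a	3825.85	26	28.45	12
SVMPIII-8b	3825.85	26	28.45	12
SVMPIII-8c	3940.07	29	26.94	12
SVMPIII-8d	3855.83	27	28.45	12
SVMPIII-8e	3848.95	25	28.45	12
SVMPIII-9a	22893.75	38	59.32	13
SVMPIII-9b	22893.75	38	59.32	13
SVMPIII-10a	1531.99	23	27.04	14
SVMPIII-10b	1531.99	23	27.04	14
SVMPIII-10c	1531.99	23	27.04	14
SVMPIII-10d	1525.10	22	27.04	14
SVMPIII-11a	6924.50	33	45.29	15
SVMPIII-11b	6893.95	32	42.91	15
SVMPIII-11c	6901.40	33	43.60	15
SVMPIII-12a	9702.24	42	56.54	16
SVMPIII-12b	9702.24	42	56.54	16
SVMPIII-13a	16451.10	38	54.15	17
SVMPIII-13b	16460.75	39	54.15	17
SVMPIII-14a	4436.73	34	39.86	18
SVMPIII-14b	4436.73	34	38.56	18
SVMPIII-14c	4442.71	37	39.86	18
Hemoglobin-b1	1105.63	6	44.22	19
SVMPIII-2	5775.72	40	39.80
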