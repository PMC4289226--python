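protein	score	peptide_matches	pct_coverage	group
SVMPIII-1	896.04	29	57.84	1
SVMPIII-2b	2805.59	26	62.77	2
SVMPIII-2a	2694.91	29	66.50	3
SVMPIII-4a	900.64	29	64.92	3
SVMPIII-4b	890.08	30	64.92	3
CRISP-1b	6457.39	23	93.67	4
CRISP-1d	6198.10	21	85.52	4
CRISP-1a	6248.59	21	87.33	5
CRISP-1c	6507.89	23	95.48	5
NatA-1	327.40	5	7.92	6
3FTx-1a	4423.76	10	78.89	7
3FTx-1b	6549.43	10	78.89	7
3FTx-1c	4423.76	10	78.89	7
3FTx-1d	6549.43	10	78.89	7
3FTx-1e	6549.43	10	78.89	7
3FTx-1f	4423.76	8	74.44	7
3FTx-3a	8140.22	6	40.22	8
3FTx-3b	8140.22	6	40.22	8
3FTx-3c	8140.22	6	40.22	8
3FTx-3d	2067.74	4	20.65	8
3FTx-3e	8140.22	6	40.22	8
3FTx-3f	8140.22	6	40.22	8
3FTx-3g	8140.22	6	40.22	8
3FTx-3h	8140.22	6	40.22	8
3FTx-3i	8140.22	6	40.22	8
3FTx-3j	6072.48	2	19.78	8
3FTx-3k	2067.74	4	20.65	8
3FTx-4a	7234.41	15	100.00	9
3FTx-4b	6945.58	13	87.21	9
3FTx-4c	5137.73	14	94.19	9
3FTx-4d	7234.41	14	92.94	9
3FTx-5	480.09	2	53.97	10
3FTx-6b	480.09	2	53.97	10
3FTx-6a	1252.34	3	53.97	11
3FTx-6c	1252.34	3	54.84	11
3FTx-7a	6785.76	11	66.67	12
3FTx-7b	6815.80	12	78.89	12
3FTx-7c	6785.76	11	66.67	12
3FTx-7d	2506.53	8	62.22	12
3FTx-8a	3911.73	9	51.11	13
3FTx-8b	3911.73	9	51.11	13
3FTx-8c	3911.73	9	51.11	13
3FTx-8d	3911.73	9	51.11	13
3FTx-8e	3911.73	9	51.11	13
3FTx-8f	3911.73	8	39.33	13
3FTx-9a	9625.12	14	81.40	14
3FTx-9b	9625.12	14	81.40	14
3FTx-9c	9625.12	14	81.40	14
3FTx-9d	9625.12	14	81.40	14
3FTx-9e	9625.12	13	69.41	14
3FTx-9f	9625.12	13	69.41	14
3FTx-9g	9625.12	14	81.40	14
3FTx-10a	3753.53	10	75.58	15
3FTx-10b	4914.06	13	91.86	15
3FTx-10c	3753.53	10	79.27	15
3FTx-10d	4914.06	12	84.71	15
3FTx-10e	4914.06	12	84.71	15
3FTx-10f	3530.34	10	69.77	15
3FTx-10g	4914.06	13	91.86	15
3FTx-10h	4914.06	13	91.86	15
3FTx-10i	4914.06	13	76.85	15
3FTx-2a	6549.43	9	55.56
3FTx-2b	6549.43	9	55.56
3FTx-2c	6549.43	9	55.56
3FTx-2d	4423.76	9	55.56
3FTx-2e	6549.43	9	55.56
3FTx-2f	5175.20	6	34.44
3FTx-2g	3049.53	6	34.44
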