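rank	cluster_name	cluster_size	cds_length	median_coverage	pct_toxin_reads	pct_total_reads
1	SVMPIII-2a	2	1836	32071	15.106	5.464
2	3FTx-9a	7	318	116501	12.923	4.674
3	3FTx-4a	4	318	101232	11.848	4.286
4	3FTx-3a	11	336	96068	9.737	3.522
5	3FTx-2a	7	330	69343	7.058	2.553
6	3FTx-10a	9	318	68918	6.897	2.495
7	3FTx-8a	6	330	63436	6.398	2.314
8	3FTx-1a	6	330	60327	6.242	2.258
9	3FTx-7a	4	330	46069	4.852	1.755
10	CRISP-1a	4	720	19816	3.835	1.387
11	SVMPIII-3a	4	1872	8563	3.647	1.319
12	SVMPIII-4a	2	1842	8043	3.471	1.256
13	SVMPIII-1	1	1842	6274	2.630	0.951
14	NP-1a	2	534	9116	1.400	0.507
15	3FTx-6a	3	255	14984	0.948	0.343
16	3FTx-5	1	255	8863	0.572	0.207
17	CTL-8a	2	495	4283	0.497	0.180
18	CTL-9a	2	483	2536	0.289	0.105
19	CTL-5	1	498	2088	0.243	0.088
20	CTL-6	1	591	1891	0.219	0.079
21	Ficolin-1a	2	996	953	0.196	0.071
22	Ficolin-3	1	996	667	0.146	0.053
23	CTL-3	1	501	1076	0.123	0.044
24	KUN-1	1	765	623	0.100	0.036
25	AChE-1	1	1818	268	0.100	0.036
26	CTL-7	1	483	808	0.090	0.033
27	Ficolin-2	1	999	403	0.083	0.030
28	AChE-2a	2	1650	186	0.063	0.023
29	PLA2-1a	2	456	408	0.042	0.015
30	CFVII	1	1278	117	0.032	0.012
31	AChE-3	1	1689	54	0.027	0.010
32	VEGF-A	1	579	190	0.025	0.009
33	Ficolin-4	1	1026	108	0.024	0.009
34	VF	1	4965	22	0.022	0.008
35	Ficolin-5	1	999	93	0.019	0.007
36	CTL-2	1	531	163	0.019	0.007
37	Waprin-2	1	408	177	0.016	0.006
38	VEGF-1	1	447	153	0.015	0.006
39	CTL-1	1	639	65	0.010	0.003
40	KUN-2	1	1542	24	0.008	0.003
41	CTL-4	1	507	59	0.007	0.003
42	HYAL	1	1344	20	0.006	0.002
43	PDE4	1	1362	18	0.005	0.002
44	CFX	1	1452	16	0.005	0.002
45	Waprin-1	1	219	82	0.004	0.002
46	VEGF-3	1	627	12	0.002	0.001
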