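rank	cluster_name	cluster_size	cds_length	median_coverage	pct_toxin_reads	pct_total_reads
1	CRISP-1a	5	720	92411	16.684	7.256
2	SVMPIII-4	1	1836	30460	11.462	4.985
3	SVMPIII-9a	2	1833	27697	10.112	4.398
4	SVMPIII-13a	2	1836	25321	10.024	4.360
5	SVMPIII-12a	2	1830	22893	8.593	3.737
6	NP-1a	12	474	56846	7.359	3.201
7	SVMPIII-3a	4	1860	16209	5.943	2.585
8	SVMPIII-7a	2	1857	11689	4.173	1.815
9	SVMPIII-11a	3	1845	10816	3.835	1.668
10	SVMPIII-8a	5	1845	9629	3.430	1.492
11	CTL-7a	5	471	32519	3.382	1.471
12	SVMPIII-6a	3	1854	7559	2.727	1.186
13	SVMPIII-5	1	1833	7058	2.693	1.171
14	CTL-8a	7	480	25070	2.633	1.145
15	SVMPIII-10a	4	1827	4941	1.687	0.734
16	SVMPIII-2	1	1827	4305	1.553	0.675
17	SVMPIII-14a	3	1839	4236	1.484	0.645
18	Fused	1	582	8844	0.960	0.418
19	SVMPIII-1	1	1857	2406	0.950	0.413
20	3FTx	1	255	1357	0.070	0.030
21	CTL-6a	2	480	640	0.060	0.026
22	KUN	1	759	423	0.056	0.024
23	CTL-5	1	477	464	0.042	0.018
24	CTL-1	1	483	304	0.029	0.013
25	CTL-3	1	495	239	0.022	0.010
26	VEGF	1	579	108	0.012	0.005
27	CTL-4	1	483	66	0.006	0.003
28	Waprin	1	405	75	0.006	0.002
29	Ficolin-1	1	1032	21	0.004	0.002
30	Ficolin-2	1	999	21	0.004	0.002
31	Vespryn	1	558	25	0.003	0.001
32	PDE4	1	1362	9	0.002	0.001
33	CTL-2	1	531	17	0.002	0.001
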