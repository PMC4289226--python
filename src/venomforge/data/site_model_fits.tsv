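toxin_set	n_seqs	m0_omega	comparison	neg_lnl_null	neg_lnl_alt	p_printed
SVMP-MP	18	1.15	M1a_vs_M2a	4092.28	4035.46	2.1e-25
SVMP-DIS	18	1.29	M1a_vs_M2a	1388.59	1357.60	3.5e-14
SVMP-ACR	18	1.39	M1a_vs_M2a	2196.52	2133.51	4.3e-28
3FTx	11	1.78	M1a_vs_M2a	1300.12	1269.82	6.9e-14
CTL	12	0.53	M1a_vs_M2a	3921.91	3902.58	4.0e-9
Ficolin	7	0.37	M1a_vs_M2a	4470.30	4458.24	5.8e-6
SVMP-MP	18	1.15	M7_vs_M8	4097.97	4036.79	2.7e-27
SVMP-DIS	18	1.29	M7_vs_M8	1389.94	1357.74	1.0e-14
SVMP-ACR	18	1.39	M7_vs_M8	2197.91	2133.66	1.2e-28
3FTx	11	1.78	M7_vs_M8	1300.92	1269.86	3.2e-14
CTL	12	0.53	M7_vs_M8	3913.45	3892.88	1.2e-9
Ficolin	7	0.37	M7_vs_M8	4468.63	4456.99	8.8e-6
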