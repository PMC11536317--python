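published_snp	qtl	published_p	candidate_snp	candidate_p	distance_bp	ld_r2
S1_3708430	QTL_1_1	0.01	S1_3708430	0.007	0	Same SNP
S1_199075640	QTL_1_2	0.95	S1_196201034	0.013	2,874,606	0.07
S1_199075673	QTL_1_2	0.95
S1_199075674	QTL_1_2	0.95
S1_199075675	QTL_1_2	0.95
S1_199075677	QTL_1_2	0.95
S1_199075679	QTL_1_2	0.95
S1_199075681	QTL_1_2	0.95
S1_199075682	QTL_1_2	0.95
S1_199075684	QTL_1_2	0.95
S1_200077059	QTL_1_3	0.35	S1_201741572	0.013	1,664,513	0.27
S1_200077088	QTL_1_3	0.35
S1_200408507	QTL_1_3	0.54
S1_200408528	QTL_1_3	0.47
S1_200479419	QTL_1_3	0.57
S1_200801543	QTL_1_3	0.27
S1_201847366	QTL_1_4	0.32	S1_201741572	0.013	105,794	0.45
S1_201872641	QTL_1_4	0.52
S1_202160398	QTL_1_4	0.44
S1_202647745	QTL_1_4	0.49
S1_279899012	QTL_1_5	0.76	S1_276323139	0.014	3,575,873	0.07
S1_298985014	QTL_1_6	0.63	S1_300073024	0.005	1,088,010	0.37
S1_298986682	QTL_1_6	0.99
S3_200876919	QTL_3_1	0.22	S3_197019251	0.020	3,857,668	0.13
S3_200876939	QTL_3_1	0.22
S3_223537342	QTL_3_2	0.19	S3_222132763	0.012	1,404,579	0.22
S3_229992268	QTL_3_3	0.63	S3_223745145	0.016	6,247,123	0.11
S4_235761612	QTL_4_1	0.47	S4_236393647	0.019	632,035	0.28
S5_128333604	QTL_5_1	0.58	S5_133776816	0.016	5,443,212	0.06
S5_128333610	QTL_5_1	0.58
S7_33885476	QTL_7_1	0.10	S7_34480421	0.012	594,945	0.76
S8_171634738	QTL_8_1	0.32	S8_173704033	0.002	2,069,295	0.17
S9_5656122	QTL_9_1	0.21	S9_5656939	0.004	817	No
S9_5656138	QTL_9_1	0.21
S9_9966270	QTL_9_2	0.08	S9_13495777	0.008	3,529,507	0.23
S9_9966272	QTL_9_2	0.08
S9_9966291	QTL_9_2	0.08
S9_11084679	QTL_9_3	0.09	S9_13495777	0.0080057	2,411,098	0.15
S9_11746822	QTL_9_4	0.52	S9_11564902	0.005	181,920	No
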