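published_snp	qtl	published_p	candidate_snp	candidate_p	distance_bp	ld_r2
S1_3708430	QTL_1_1	0.007	S1_3197323	0.014	511,107	0.39
S1_199075640	QTL_1_2	0.953	S1_200288001	0.014	1,212,361	0.37
S1_199075673	QTL_1_2	0.953
S1_199075674	QTL_1_2	0.953
S1_199075675	QTL_1_2	0.953
S1_199075677	QTL_1_2	0.953
S1_199075679	QTL_1_2	0.953
S1_199075681	QTL_1_2	0.953
S1_199075682	QTL_1_2	0.953
S1_199075684	QTL_1_2	0.953
S1_200077059	QTL_1_3	0.353	S1_200288001	0.014	210,942	0.46
S1_200077088	QTL_1_3	0.353
S1_200408507	QTL_1_3	0.545
S1_200408528	QTL_1_3	0.471
S1_200479419	QTL_1_3	0.572
S1_200801543	QTL_1_3	0.270
S1_201847366	QTL_1_4	0.319	S1_201872818	0.008	25,452	0.68
S1_201872641	QTL_1_4	0.521
S1_202160398	QTL_1_4	0.440
S1_202647745	QTL_1_4	0.490
S1_279899012	QTL_1_5	0.762	S1_280826390	0.017	927,378	0.07
S1_298985014	QTL_1_6	0.628	S1_299470567	0.008	483,885	0.12
S1_298986682	QTL_1_6	0.985
S3_200876919	QTL_3_1	0.220	S3_199293659	0.010	1,583,260	0.10
S3_200876939	QTL_3_1	0.220
S3_223537342	QTL_3_2	0.192	S3_225038503	0.004	1,501,161	0.459
S3_229992268	QTL_3_3	0.634	S3_228983201	0.009	1,009,067	0.133
S4_235761612	QTL_4_1	0.466	S4_235381320	0.020	380,292	0.531
S5_128333604	QTL_5_1	0.583	S5_135433904	0.018	7,100,300	0.537
S5_128333610	QTL_5_1	0.583
S7_33885476	QTL_7_1	0.101	S7_23960799	0.016	9,924,677	0.227
S8_171634738	QTL_8_1	0.323	S8_171625362	0.013	9,376	0.06
S9_5656122	QTL_9_1	0.207	S9_8039883	0.011	2,383,761	No
S9_5656138	QTL_9_1	0.207
S9_9966270	QTL_9_2	0.082	S9_8039883	0.011	1,926,387	0.1
S9_9966272	QTL_9_2	0.082
S9_9966291	QTL_9_2	0.082
S9_11084679	QTL_9_3	0.086	S9_13662469	0.011	2,577,790	0.32
S9_11746822	QTL_9_4	0.525	S9_12599906	0.00696272	853,084	No
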