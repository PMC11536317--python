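published_snp	qtl	published_p	candidate_snp	candidate_p	distance_bp	ld_r2
S1_19252698	QTL_1_1	0.25	S1_18200092	0.002	1,052,606	0.22
S1_290934634	QTL_1_2	0.60	S1_290306138	0.004	628,496	0.01
S2_14798875	QTL_2_1	0.01	S2_14798875	0.009	0	Same SNP
S2_179803199	QTL_2_2	0.09	S2_180155965	0.015	352,766	0.77
S3_191332395	QTL_3_1	0.94	S3_190325618	0.018	1,006,777	0.45
S3_212770896	QTL_3_2	0.74	S3_212771115	0.004	219	0.15
S3_218807815	QTL_3_3	0.99	S3_218835769	0.018	27,954	0.31
S3_218807820	QTL_3_3	0.99
S4_127856740	QTL_4_1	0.59	S4_131837902	0.014	3,981,162	0.11
S4_127955231	QTL_4_1	0.69
S4_155128691	QTL_4_2	0.87	S4_154625109	0.003	503,582	0.21
S4_155830369	QTL_4_3	0.20	S4_154625109	0.003	1,205,260	0.39
S4_155830370	QTL_4_3	0.20
S4_155830400	QTL_4_3	0.20
S4_156193095	QTL_4_4	0.32	S4_156023370	0.006	169,725	0.02
S4_181340312	QTL_4_5	0.22	S4_201364747	0.016	20,024,435	0.21
S4_221752511	QTL_4_6	0.10	S4_222702242	0.019	949,731	No
S5_24771445	QTL_5_1	0.18	S5_33610351	0.016	8,838,906	0.38
S6_147725553	QTL_6_1	0.17	S6_147968131	0.011	242,578	1.00
S6_150800759	QTL_6_2	0.07	S6_150889722	0.011	88,963	0.68
S6_156035854	QTL_6_3	0.47	S6_156282464	0.017	246,610	0.69
S6_164776991	QTL_6_4	0.28	S6_160234735	0.013	4,542,256	0.33
S7_109722251	QTL_7_1	0.15	S7_112215633	0.005	2,493,382	0.42
S8_24527783	QTL_8_1	0.40	S8_26089118	0.016	1,561,335	0.01
S8_28525990	QTL_8_2	0.81	S8_26089118	0.016	2,436,872	0.03
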