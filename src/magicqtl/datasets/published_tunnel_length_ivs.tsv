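published_snp	qtl	published_p	candidate_snp	candidate_p	distance_bp	ld_r2
S1_19252698	QTL_1_1	0.12	S1_18978470	0.013	274,228	0.26
S1_290934634	QTL_1_2	0.13	S1_292415110	0.004	1,480,476	0.06
S2_14798875	QTL_2_1	0.15	S2_15140966	0.016	342,091	0.65
S2_179803199	QTL_2_2	0.68	S2_185171168	0.011	5,367,969	0.18
S3_191332395	QTL_3_1	0.16	S3_191368808	0.017	36,413	0.65
S3_212770896	QTL_3_2	0.86	S3_212502290	0.003	268,606	0.08
S3_218807815	QTL_3_3	0.66	S3_216256039	0.008	2,551,776	0.20
S3_218807820	QTL_3_3	0.66
S4_127856740	QTL_4_1	0.35	S4_111050431	0.018	16,806,309	0.61
S4_127955231	QTL_4_1	0.38
S4_155128691	QTL_4_2	0.94	S4_158606264	0.007	3,477,573	0.02
S4_155830369	QTL_4_3	0.37	S4_153520875	0.014	2,309,494	0.02
S4_155830370	QTL_4_3	0.37
S4_155830400	QTL_4_3	0.37
S4_156193095	QTL_4_4	0.27	S4_156718547	0.018	525,452	0.09
S4_181340312	QTL_4_5	0.86	S4_181696701	0.007	356,389	0.12
S4_221752511	QTL_4_6	0.73	S4_222716155	0.014	963,644	0.04
S5_24771445	QTL_5_1	0.09	S5_23764335	0.011	1,007,110	0.40
S6_147725553	QTL_6_1	0.93	S6_148774898	0.009	1,049,345	0.21
S6_150800759	QTL_6_2	0.15	S6_150697524	0.006	103,235	0.34
S6_156035854	QTL_6_3	0.14	S6_155739471	0.019	296,383	0.23
S6_164776991	QTL_6_4	0.85	S6_166815163	0.011	2,038,172	0.23
S7_109722251	QTL_7_1	0.87	S7_112219931	0.008	2,497,680	0.32
S8_24527783	QTL_8_1	0.96	S8_27642137	0.011	3,114,354	0.13
S8_28525990	QTL_8_2	0.66	S8_27642137	0.018	883,853	0.23
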