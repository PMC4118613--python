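trait	marker	linkage_group	n_genotypes	a1	a2	d	R2
Height	PMSNP01036	7	2	5.88	-	-	0.03
Height	PMSNP01033	7	2	6.88	-	-	0.04
Diameter	PMSNP00162	8	2	0.12	-	-	0.02
Diameter	PMSNP00095	8	2	0.13	-	-	0.03
Diameter	PMSNP00545	3	3	0.02	-	0.30	0.11
Stem Taper	PMSNP00095	8	2	0.12	-	-	0.03
Stem Taper	PMSNP00082	8	2	0.11	-	-	0.03
Stem Taper	PMSNP00071	8	2	0.13	-	-	0.03
Stem Taper	PMSNP00068	8	2	0.11	-	-	0.03
Stem Taper	PMSNP00021	3	3	0.14	-	-	0.03
Leaf Length	PMSNP01203	4	2	1.45	-	-	0.03
Leaf Length	PMSNP00307	5	2	1.76	-	-	0.04
Leaf Length	PMSNP00457	5	3	2.15	-	1.23	0.10
Leaf Length	PMSNP01407	6	2	1.52	-	-	0.03
Leaf Width	PMSSR0620	5	4	1.00	1.96	0.04	0.08
Leaf Width	PMSSR0358	5	4	1.27	1.74	0.32	0.09
Leaf Width	PMSNP00349	5	3	3.07	-	0.59	0.15
Leaf Width	PMSNP00453	5	3	2.74	-	0.44	0.14
Leaf Width	PMSNP00470	5	3	-2.79	-	-0.11	0.13
Leaf Area	PMSSR0620	5	4	-0.46	-1.06	0.06	0.08
Leaf Area	PMSSR0358	5	4	0.72	0.92	0.10	0.07
Leaf Petiole	PMSNP00815	2	2	0.54	-	-	0.03
Leaf Petiole	PMSNP00818	2	2	0.51	-	-	0.03
Leaf Petiole	PMSNP00821	2	2	0.51	-	-	0.03
Leaf Shape	PMSSR0128	5	4	0.015	0.011	0.010	0.03
Leaf Shape	PMSNP01299	1	2	0.017	-	-	0.02
Leaf Shape	PMSNP01309	1	2	0.019	-	-	0.03
Leaf Shape	PMSNP00463	5	2	0.018	-	-	0.02
Leaf Shape	PMSNP00349	5	3	0.027	-	0.013	0.07
Leaf Shape	PMSNP00448	5	3	-0.027	-	0.010	0.06
Vein Number	PMSNP00307	5	2	-0.43	-	-	0.03
Vein Number	PMSNP01379	1	2	0.42	-	-	0.03
Vein Number	PMSNP01140	4	2	0.42	-	-	0.03
Vein Number	PMSNP01126	4	2	0.43	-	-	0.03
Vein Number	PMSNP01122	4	2	0.46	-	-	0.03
Vein Number	PMSNP01461	6	3	0.73	-	0.42	0.10
Vein Density	PMSNP00271	5	2	0.073	-	-	0.03
Vein Density	PMSNP00281	5	2	0.078	-	-	0.04
Vein Density	PMSNP00285	5	2	0.076	-	-	0.03
Vein Density	PMSNP00288	5	2	0.076	-	-	0.04
Vein Density	PMSNP00289	5	2	-0.074	-	-	0.03
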