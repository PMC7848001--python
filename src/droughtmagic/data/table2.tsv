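trait	snp_id	chrom	pos	lod	maf
grain_yield	2_31564	6	32057972	3.35	9.64
grain_yield	2_31565	6	32058239	3.35	9.64
grain_yield	2_30808	6	32061499	3.35	9.64
grain_yield	2_19053	6	32061827	3.35	9.64
grain_yield	2_33474	6	32070478	3.35	9.64
grain_yield	2_28131	6	32077832	3.35	9.64
grain_yield	2_28570	6	32088910	3.09	9.80
grain_yield	2_10632	6	32089786	3.35	9.64
grain_yield	2_13247	6	32107028	3.35	9.64
grain_yield	2_18126	6	32147410	3.35	9.64
grain_yield	2_14728	6	32165112	3.35	9.64
grain_yield	2_02004	6	32184138	3.35	9.64
grain_yield	2_25332	6	32186496	3.35	9.64
grain_yield	2_33745	6	32186893	3.35	9.64
grain_yield	2_25331	6	32188321	3.35	9.64
grain_yield	2_25334	6	32189396	3.51	8.23
grain_yield	2_25333	6	32189710	3.35	9.64
grain_yield	2_30533	6	32204324	3.35	9.64
grain_yield	2_31969	6	32234310	3.35	9.64
grain_yield	2_32622	6	32239677	3.35	9.64
grain_yield	2_50666	6	32250975	3.11	9.92
grain_yield	2_21574	6	32454860	3.05	9.64
grain_yield	2_29076	6	32461137	3.05	9.64
grain_yield	1_0823	6	32612013	3.05	9.64
grain_yield	2_15103	6	32612013	3.05	9.64
grain_yield	2_21155	6	32624482	3.05	9.64
grain_yield	2_53988	8	21904122	3.15	11.24
grain_yield	2_46582	8	22607265	3.29	11.65
grain_yield	2_01303	9	4760699	3.24	13.25
grain_yield	2_51818	9	4789752	3.38	12.85
grain_yield	2_35898	9	4877591	3.16	13.65
grain_yield	2_23949	9	5346101	3.26	14.46
grain_yield	2_23950	9	5347304	3.26	14.46
grain_yield	2_11952	9	5364438	3.26	14.46
grain_yield	2_34102	9	7298753	3.08	9.79
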