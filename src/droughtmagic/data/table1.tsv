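trait	snp_id	chrom	pos	lod	maf
habit_change	2_40797	8	10549370	3.06	12.05
habit_change	2_42112	8	10601329	3.06	12.05
habit_change	2_42607	8	11012105	3.41	31.33
habit_change	2_26924	8	13771284	4.06	17.67
habit_change	2_01300	8	14264077	3.88	17.27
habit_change	2_10658	8	15346859	3.88	17.27
habit_change	2_54501	8	16564006	3.88	17.27
habit_change	2_45332	8	16871228	3.88	17.27
habit_change	2_06275	8	17354751	3.88	17.27
habit_change	2_43529	8	20159451	3.64	17.67
habit_change	2_40435	8	20618849	3.64	17.67
habit_change	2_50806	10	29754489	3.49	12.20
habit_change	2_26782	10	30148065	3.38	13.25
habit_change	2_38918	10	30517553	3.25	13.31
maturity	2_16403	2	32138108	3.13	42.17
maturity	2_45148	2	32146045	3.13	42.17
maturity	2_55009	7	14098180	3.54	13.65
maturity	2_51274	7	14976910	3.54	13.65
maturity	2_21981	8	1801037	5.68	20.08
maturity	2_10862	8	1929122	3.20	33.33
maturity	2_10861	8	1929370	3.20	33.33
maturity	1_0806	8	1950113	3.00	32.93
maturity	2_21676	8	1965506	3.00	32.93
maturity	2_21804	8	1970485	3.00	32.93
maturity	2_23871	8	1980059	3.00	32.93
maturity	2_23870	8	1980643	3.00	32.93
maturity	2_44136	8	1985249	3.00	32.93
maturity	2_14976	8	2006627	4.23	28.92
maturity	2_40337	8	2013873	4.27	28.34
maturity	2_14158	8	2338417	3.63	33.33
maturity	2_16735	8	2361920	3.47	32.93
maturity	2_41533	8	2384266	3.34	33.20
flowering	2_06470	3	62407410	2.84	12.45
flowering	2_52919	3	62409665	2.84	12.45
flowering	2_06137	3	62434051	2.84	12.45
flowering	1_0946	3	63722355	2.83	11.65
flowering	2_27706	8	37928961	2.83	19.68
seed_weight	2_11122	4	1483784	2.95	11.34
seed_weight	2_03731	4	1523145	2.89	10.84
seed_weight	2_14932	4	1548833	2.89	10.84
seed_weight	2_34365	4	1549730	2.89	10.84
seed_weight	2_07882	4	1556026	2.89	10.84
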