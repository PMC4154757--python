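probe_id	accession	gene_symbol	p_anova	p_logrank	p_integrated	p_adjusted_display
200832_s_at	AB032261	SCD1	2.47E-06	6.06E-03	1.50E-08	6.70E-04
200887_s_at	NM_007315	STAT1	1.17E-04	1.91E-02	2.24E-06	3.59E-02
201231_s_at	NM_001428	ENO1/MBP1	2.27E-08	1.06E-03	2.40E-11	<1.00E-05
201508_at	NM_001552	IGFBP4	3.21E-06	4.01E-02	1.29E-07	3.76E-03
202236_s_at	NM_003051	SLC16A1/MCT1	1.12E-04	6.93E-04	7.77E-08	2.34E-03
202870_s_at	NM_001255	CDC20	9.26E-07	6.28E-03	5.81E-09	2.90E-04
203065_s_at	NM_001753	CAV1	1.33E-10	3.28E-02	4.35E-12	<1.00E-05
203323_at	BF197655	CAV2	5.67E-10	2.35E-02	1.33E-11	<1.00E-05
203554_x_at	NM_004219	PTTG1	7.33E-09	5.64E-03	4.13E-11	<1.00E-05
207011_s_at	NM_002821	PTK7	2.57E-07	1.89E-02	4.86E-09	2.70E-04
207168_s_at	NM_004893	H2AFY/H2AX	2.83E-05	1.80E-02	5.11E-07	1.19E-02
207543_s_at	NM_000917	P4HA1	1.06E-08	5.73E-04	6.06E-12	<1.00E-05
208680_at	L19184	PRDX1	5.73E-08	1.64E-02	9.37E-10	6.00E-05
208694_at	U47077	PRKDC/DNA-PKcs	1.71E-04	1.31E-02	2.25E-06	3.60E-02
208767_s_at	AW149681	LAPTM4B	5.47E-05	1.65E-02	9.04E-07	1.81E-02
209030_s_at	NM_014333	CADM1/TSLC1	1.80E-10	4.20E-02	7.59E-12	<1.00E-05
209031_at	AL519710	CADM1/TSLC1	2.10E-11	5.68E-03	1.19E-13	<1.00E-05
209543_s_at	M81104	CD34	2.66E-06	1.54E-02	4.10E-08	1.33E-03
210495_x_at	AF130095	FN1	3.90E-08	1.78E-02	6.96E-10	2.00E-05
210559_s_at	D88357	CDK1/CDC2	7.69E-07	4.30E-02	3.31E-08	1.14E-03
212097_at	AU147399	CAV1	1.54E-09	2.95E-03	4.53E-12	<1.00E-05
212464_s_at	X02761	FN1	1.93E-08	1.78E-02	3.44E-10	1.00E-05
217294_s_at	U88968	ENO1/MBP1	8.81E-08	2.33E-02	2.05E-09	1.50E-04
217871_s_at	NM_002415	MIF	5.67E-08	1.46E-02	8.29E-10	5.00E-05
218308_at	NM_006342	TACC3	2.82E-05	2.26E-02	6.38E-07	1.40E-02
218502_s_at	NM_014112	TRPS1	1.48E-18	3.99E-02	5.90E-20	<1.00E-05
218755_at	NM_005733	KIF20A/MKlp2	3.01E-06	2.02E-02	6.08E-08	1.94E-03
219918_s_at	NM_018123	ASPM	1.22E-05	1.64E-02	2.00E-07	5.51E-03
220942_x_at	NM_014367	FAM162A/HGTD-P	4.44E-05	3.21E-02	1.42E-06	2.56E-02
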