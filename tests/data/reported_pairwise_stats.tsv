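probe_id	gene_symbol	p_UPS_MFS	q_UPS_MFS	p_UPS_SS	q_UPS_SS	p_UPS_MLS	q_UPS_MLS
200832_s_at	SCD1	7.36E-05	8.87E-04	1.06E-03	2.56E-03	3.52E-01	4.26E-01
200887_s_at	STAT1	2.81E-01	4.07E-01	1.54E-03	3.19E-03	2.04E-01	2.69E-01
201231_s_at	ENO1/MBP1	1.06E-04	8.87E-04	4.73E-08	6.85E-07	4.27E-06	1.42E-05
201508_at	IGFBP4	4.21E-02	1.15E-01	7.39E-03	1.13E-02	7.25E-02	1.00E-01
202236_s_at	SLC16A1/MCT1	1.54E-01	2.80E-01	3.92E-01	4.06E-01	6.49E-04	1.25E-03
202870_s_at	CDC20	2.10E-01	3.58E-01	1.23E-03	2.74E-03	6.26E-06	1.78E-05
203065_s_at	CAV1	8.76E-01	8.76E-01	5.56E-07	2.69E-06	5.31E-01	5.93E-01
203323_at	CAV2	8.45E-01	8.75E-01	6.14E-05	1.98E-04	1.26E-03	2.15E-03
203554_x_at	PTTG1	3.76E-01	4.96E-01	8.95E-05	2.60E-04	1.59E-08	2.31E-07
207011_s_at	PTK7	6.14E-03	2.23E-02	4.21E-03	6.78E-03	9.19E-01	9.19E-01
207168_s_at	H2AFY/H2AX	4.37E-02	1.15E-01	1.18E-01	1.37E-01	6.75E-06	1.78E-05
207543_s_at	P4HA1	1.22E-04	8.87E-04	2.64E-02	3.48E-02	2.51E-03	4.05E-03
208680_at	PRDX1	1.84E-03	7.61E-03	5.31E-05	1.93E-04	1.36E-08	2.31E-07
208694_at	PRKDC/DNA-PKcs	5.49E-02	1.33E-01	9.76E-01	9.76E-01	1.13E-03	2.06E-03
208767_s_at	LAPTM4B	4.20E-01	5.30E-01	3.73E-02	4.60E-02	8.30E-03	1.27E-02
209030_s_at	CADM1/TSLC1	2.49E-01	3.80E-01	2.81E-07	1.82E-06	6.43E-01	6.66E-01
209031_at	CADM1/TSLC1	6.04E-02	1.35E-01	2.67E-07	1.82E-06	2.71E-01	3.42E-01
209543_s_at	CD34	8.73E-03	2.81E-02	1.78E-01	1.91E-01	3.97E-05	8.22E-05
210495_x_at	FN1	4.83E-01	5.61E-01	2.50E-03	4.27E-03	3.53E-06	1.42E-05
210559_s_at	CDK1/CDC2	7.05E-02	1.46E-01	2.35E-02	3.24E-02	3.57E-06	1.42E-05
212097_at	CAV1	6.43E-01	6.91E-01	3.14E-07	1.82E-06	4.16E-01	4.83E-01
212464_s_at	FN1	5.22E-01	5.83E-01	2.33E-03	4.22E-03	2.07E-06	1.20E-05
217294_s_at	ENO1/MBP1	4.24E-04	2.46E-03	4.07E-05	1.69E-04	1.55E-07	1.50E-06
217871_s_at	MIF	5.31E-06	1.54E-04	1.38E-01	1.54E-01	1.35E-05	3.27E-05
218308_at	TACC3	2.36E-01	3.80E-01	7.67E-04	2.02E-03	2.91E-05	6.49E-05
218502_s_at	TRPS1	3.64E-01	4.96E-01	5.21E-11	1.51E-09	1.85E-02	2.68E-02
218755_at	KIF20A/MKlp2	4.44E-01	5.37E-01	9.97E-03	1.45E-02	4.41E-06	1.42E-05
219918_s_at	ASPM	1.11E-01	2.15E-01	2.25E-03	4.22E-03	7.89E-07	5.72E-06
220942_x_at	FAM162A/HGTD-P	1.39E-03	6.70E-03	3.81E-02	4.60E-02	6.23E-01	6.66E-01
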