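gene	division	category	basement_membrane	mean_intensity
COL4A2	Core matrisome	Collagens	1	2.0E+07
COL6A3	Core matrisome	Collagens	1	9.5E+06
COL1A2	Core matrisome	Collagens	0	6.6E+06
COL6A1	Core matrisome	Collagens	1	3.0E+06
COL4A1	Core matrisome	Collagens	1	2.5E+06
COL1A1	Core matrisome	Collagens	0	2.3E+06
COL18A1	Core matrisome	Collagens	1	2.0E+06
COL12A1	Core matrisome	Collagens	0	9.2E+05
COL15A1	Core matrisome	Collagens	1	4.3E+05
COL14A1	Core matrisome	Collagens	0	1.7E+05
COL4A6	Core matrisome	Collagens	1	6.8E+04
LAMB2	Core matrisome	ECM Glycoproteins	1	4.4E+07
LAMC1	Core matrisome	ECM Glycoproteins	1	3.2E+07
LAMA5	Core matrisome	ECM Glycoproteins	1	1.5E+07
NID1	Core matrisome	ECM Glycoproteins	1	1.3E+07
LAMA2	Core matrisome	ECM Glycoproteins	1	1.3E+07
AGRN	Core matrisome	ECM Glycoproteins	1	1.2E+07
FN1	Core matrisome	ECM Glycoproteins	0	9.1E+06
NID2	Core matrisome	ECM Glycoproteins	1	8.7E+06
TINAGL1	Core matrisome	ECM Glycoproteins	0	8.5E+06
FGG	Core matrisome	ECM Glycoproteins	0	7.2E+06
FGA	Core matrisome	ECM Glycoproteins	0	2.1E+06
LAMA1	Core matrisome	ECM Glycoproteins	1	1.8E+06
LAMA4	Core matrisome	ECM Glycoproteins	1	1.5E+06
VWA1	Core matrisome	ECM Glycoproteins	0	1.2E+06
EMILIN1	Core matrisome	ECM Glycoproteins	0	9.7E+05
LAMC3	Core matrisome	ECM Glycoproteins	1	8.2E+05
VWA7	Core matrisome	ECM Glycoproteins	0	7.7E+05
ELN	Core matrisome	ECM Glycoproteins	0	7.3E+05
LAMB1	Core matrisome	ECM Glycoproteins	0	7.0E+05
VWF	Core matrisome	ECM Glycoproteins	0	5.6E+05
TNXB	Core matrisome	ECM Glycoproteins	0	4.5E+05
MMRN2	Core matrisome	ECM Glycoproteins	0	4.1E+05
FBN1	Core matrisome	ECM Glycoproteins	0	3.5E+05
TNR	Core matrisome	ECM Glycoproteins	0	3.1E+05
SBSPON	Core matrisome	ECM Glycoproteins	0	1.5E+05
LAMA3	Core matrisome	ECM Glycoproteins	1	1.5E+05
PAPLN	Core matrisome	ECM Glycoproteins	1	1.1E+05
MFAP1	Core matrisome	ECM Glycoproteins	0	1.2E+04
DSP	Core matrisome	ECM Glycoproteins	0	9.4E+04
EFEMP1	Core matrisome	ECM Glycoproteins	0	8.2E+04
LGI3	Core matrisome	ECM Glycoproteins	0	6.6E+04
TGFBI	Core matrisome	ECM Glycoproteins	0	3.5E+04
PXN	Core matrisome	ECM Glycoproteins	0	3.0E+04
LTBP1	Core matrisome	ECM Glycoproteins	0	2.3E+04
MATN2	Core matrisome	ECM Glycoproteins	0	2.2E+04
EDIL3	Core matrisome	ECM Glycoproteins	0	2.6E+03
HSPG2	Core matrisome	Proteoglycans	1	2.2E+07
HAPLN2	Core matrisome	Proteoglycans	0	5.5E+05
BGN	Core matrisome	Proteoglycans	0	3.9E+05
DCN	Core matrisome	Proteoglycans	0	3.8E+05
VCAN	Core matrisome	Proteoglycans	0	8.1E+04
PRELP	Core matrisome	Proteoglycans	0	6.1E+04
ANXA1	Matrisome-associated	ECM-affiliated Proteins	0	7.8E+05
LGALS9	Matrisome-associated	ECM-affiliated Proteins	0	2.2E+05
LGALS1	Matrisome-associated	ECM-affiliated Proteins	0	4.7E+04
ANXA6	Matrisome-associated	ECM-affiliated Proteins	0	3.6E+04
ANXA5	Matrisome-associated	ECM-affiliated Proteins	0	3.1E+04
ANXA2	Matrisome-associated	ECM-affiliated Proteins	0	2.7E+04
ANXA7	Matrisome-associated	ECM-affiliated Proteins	0	6.2E+03
TGM2	Matrisome-associated	ECM Regulators	0	4.2E+06
CTSD	Matrisome-associated	ECM Regulators	0	1.1E+06
CAP2	Matrisome-associated	ECM Regulators	0	3.7E+05
SERPINH1	Matrisome-associated	ECM Regulators	0	1.1E+05
TIMP3	Matrisome-associated	ECM Regulators	0	3.2E+05
PLAT	Matrisome-associated	ECM Regulators	0	1.1E+05
HTRA1	Matrisome-associated	ECM Regulators	0	5.7E+04
PC	Matrisome-associated	Secreted Factors	0	1.9E+06
LMNB2	Matrisome-associated	Secreted Factors	0	1.0E+06
MLF2	Matrisome-associated	Secreted Factors	0	2.2E+05
NBN	Matrisome-associated	Secreted Factors	0	1.3E+05
HCFC1	Matrisome-associated	Secreted Factors	0	1.2E+05
RIF1	Matrisome-associated	Secreted Factors	0	1.0E+05
S100A8	Matrisome-associated	Secreted Factors	0	9.2E+04
STK3	Matrisome-associated	Secreted Factors	0	8.5E+04
ZFP91-CNTF	Matrisome-associated	Secreted Factors	0	5.6E+04
HCFC2	Matrisome-associated	Secreted Factors	0	2.6E+04
MIF	Matrisome-associated	Secreted Factors	0	7.6E+03
EGFL8	Matrisome-associated	Secreted Factors	0	4.0E+03
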