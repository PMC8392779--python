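gene	division	category	basement_membrane	mean_intensity
Col4a2	Core matrisome	Collagens	1	8.7E+06
Col1a1	Core matrisome	Collagens	0	4.7E+06
Col6a3	Core matrisome	Collagens	1	2.1E+06
Col6a1	Core matrisome	Collagens	1	1.3E+06
Col18a1	Core matrisome	Collagens	1	1.2E+06
Col1a2	Core matrisome	Collagens	0	5.9E+05
Col4a1	Core matrisome	Collagens	1	4.8E+05
Col6a2	Core matrisome	Collagens	1	4.8E+05
Col12a1	Core matrisome	Collagens	0	2.1E+05
Col15a1	Core matrisome	Collagens	1	1.4E+05
Lamc1	Core matrisome	ECM Glycoproteins	1	3.2E+07
Lamb2	Core matrisome	ECM Glycoproteins	1	3.2E+07
Lama5	Core matrisome	ECM Glycoproteins	1	1.1E+07
Nid1	Core matrisome	ECM Glycoproteins	1	1.0E+07
Agrn	Core matrisome	ECM Glycoproteins	1	7.8E+06
Tinagl1	Core matrisome	ECM Glycoproteins	0	5.3E+06
Nid2	Core matrisome	ECM Glycoproteins	1	5.2E+06
Lama2	Core matrisome	ECM Glycoproteins	1	4.4E+06
Lama1	Core matrisome	ECM Glycoproteins	1	3.3E+06
Vwa1	Core matrisome	ECM Glycoproteins	0	2.5E+06
Lama4	Core matrisome	ECM Glycoproteins	1	2.0E+06
Lamb1	Core matrisome	ECM Glycoproteins	1	1.4E+06
Vwf	Core matrisome	ECM Glycoproteins	0	1.4E+05
Lamc3	Core matrisome	ECM Glycoproteins	1	9.8E+04
Tnr	Core matrisome	ECM Glycoproteins	0	8.5E+04
Lama3	Core matrisome	ECM Glycoproteins	1	7.9E+04
Mmrn2	Core matrisome	ECM Glycoproteins	0	5.1E+04
Ltbp4	Core matrisome	ECM Glycoproteins	0	4.9E+04
Emilin1	Core matrisome	ECM Glycoproteins	0	4.4E+04
Dsp	Core matrisome	ECM Glycoproteins	0	4.3E+04
Vtn	Core matrisome	ECM Glycoproteins	0	2.8E+04
Papln	Core matrisome	ECM Glycoproteins	1	2.2E+04
Fbln5	Core matrisome	ECM Glycoproteins	0	1.7E+04
Lgi3	Core matrisome	ECM Glycoproteins	0	1.6E+04
Lgi1	Core matrisome	ECM Glycoproteins	0	1.1E+04
Sbspon	Core matrisome	ECM Glycoproteins	0	5.8E+03
Mfap1	Core matrisome	ECM Glycoproteins	0	8.2E+04
Dcn	Core matrisome	Proteoglycans	0	5.2E+04
Bgn	Core matrisome	Proteoglycans	0	3.8E+04
Prelp	Core matrisome	Proteoglycans	0	2.5E+04
Hapln1	Core matrisome	Proteoglycans	0	2.1E+04
Ncan	Core matrisome	Proteoglycans	0	1.2E+04
Gpc5	Matrisome-associated	ECM-affiliated Proteins	0	6.2E+04
Sdc4	Matrisome-associated	ECM-affiliated Proteins	0	5.7E+04
Gpc4	Matrisome-associated	ECM-affiliated Proteins	0	2.6E+04
Gpc1	Matrisome-associated	ECM-affiliated Proteins	0	9.2E+03
Anxa2	Matrisome-associated	ECM-affiliated Proteins	0	8.1E+03
Itih5	Matrisome-associated	ECM Regulators	0	9.2E+05
Tgm2	Matrisome-associated	ECM Regulators	0	6.0E+05
Gm5409	Matrisome-associated	ECM Regulators	0	3.0E+05
Serpinh1	Matrisome-associated	ECM Regulators	0	1.1E+05
Sart1	Matrisome-associated	Secreted Factors	0	8.4E+04
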