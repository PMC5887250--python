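gene	transcript_id	variant_no	formulas	human_specific_transcript
ADCY6	ENST00000307885.4	201	- 48 (CCA)3	0
AMY1C	ENST00000370079.3	201	- 79 (ATT)3	1
APBB1	ENST00000311051.7	202	- 11 (GCC)3	0
BRINP2	ENST00000361539.4	201	- 26 (GGC)5	0
BVES	ENST00000446408.2	203	- 35 (CCT)3	0
CCDC178	ENST00000300227.12	201	- 79 (AGC)3;- 57 (CGC)5	0
CDH4	ENST00000543233.2	201	- 31 (CCT)3	0
CIAPIN1	ENST00000563341.1	202	- 39 (CCT)3	0
CNTNAP2	ENST00000361727.7	201	- 98 (TGC)3	0
CST4	ENST00000217423.3	201	- 83 (GGA)3	0
CYP4A11	ENST00000310638.8	201	- 86 (CCT)3	0
C1orf204	ENST00000368102.5	201	- 11 (AAG)3	1
C22orf24	NM_015372.2	1	- 98 (GCA)3	1
C3AR1	ENST00000546241.1	202	- 70 (AGA)3	0
DDX58	ENST00000379868.5	201	- 33 (CCT)3	1
ECSCR	NM_001077693.3	1	- 121 (CCA)3	1
GRIN2D	ENST00000263269.3	201	- 67 (GCC)3	0
GSDMB	ENST00000394175.6	203	- 55 (GGC)3	0
INPP4B	ENST00000503927.5	202	- 88 (CGC)3	0
KBTBD12	ENST00000407609.7	204	- 57 (CCT)3	0
KIAA1211	ENST00000504228.5	203	- 81 (AAG)3	0
KRAS	ENST00000311936.7	202	- 89 (GAA)3	0
KTN1	ENST00000395308.5	202	- 70 (GCG)9	0
LACTBL1	ENST00000426928.6	201	- 58 (GAA)3	0
LCE2B	ENST00000368780.3	201	- 79 (CCT)3	1
LCOR	ENST00000356016.7	202	- 97 (CCT)3;- 108 (GCC)3	0
MPRIP	ENST00000466186.2	209	- 88 (GCA)11	1
MSANTD3	ENST00000374885.5	201	- 25 (GCC)7	0
NPAS1	ENST00000439365.6	201	- 135 (GAA)9	1
OR4X1	ENST00000320048.1	201	- 100 (GAT)3	0
PABPC1L2B	ENST00000373521.3	201	- 60 (GCC)3	0
PAQR9	ENST00000498470.1	203	- 29 (TGC)3	1
PRSS1	ENST00000492062.1	205	- 96 (GAT)3	1
RGPD6	ENST00000455695.1	205	- 70 (GGC)5	1
RNF215	ENST00000215798.10	201	- 123 (GCT)5	0
R3HDM2	ENST00000448732.1	208	- 27 (GCC)3	1
SCN3B	ENST00000299333.7	201	- 29 (GGT)3	0
SERPINB9	ENST00000380698.4	201	- 12 (GCA)3	0
SIGLEC7	ENST00000305628.7	201	- 80 (TTC)3	0
SPATC1L	ENST00000330205.10	202	- 37 (TGG)4;- 90 (TGG)4	0
STUB1	ENST00000219548.8	201	- 91 (GCC)3	0
SUMF1	ENST00000272902.9	201	- 102 (AGC)3	0
TEX12	ENST00000280358.4	201	- 105 (TGG)3	0
TMEM99	ENST00000301665.7	201	- 32 (CCG)3;- 47 (CCG)3;- 59 (CCG)3;- 83 (CCG)3;- 110 (CCG)3;- 125 (CCG)3;- 48 (GCC)3;- 60 (GCC)3;- 84 (GCC)3;- 126 (GCC)3	1
TNNC2	ENST00000372557.1	202	- 53 (GCC)3	0
TPTE	ENST00000427445.6	201	- 110 (GCG)3	0
TRBJ2-7	ENST00000390419.1	201	- 120 (GGC)3	0
TRGV5	NC_000007.14:TRGV5:u_t_1	1	- 48 (CTC)3	0
TRIM39	ENST00000376656.8	201	- 58 (CCT)4	0
UAP1	ENST00000367926.8	204	- 9 (CGT)3	0
VNN2	ENST00000326499.10	201	- 31 (GAA)10	0
WRN	NM_000553.4	1	- 67 (GCC)3;- 69 (CCG)4;- 92 (GCC)3	0
WRNIP1	ENST00000618555.4	205	- 67 (CCG)3	0
ZDHHC21	XM_006716760.1	1	- 32 (AGG)3	0
ZSCAN30	ENST00000639929.1	212	- 57 (GAA)3	1
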