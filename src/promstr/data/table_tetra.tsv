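gene	transcript_id	variant_no	formulas	human_specific_transcript
ARHGAP5	ENST00000345122.7	202	- 110 (GGGA)4	0
ARHGEF35	ENST00000378115.2	201	- 22 (TCCC)3	1
ARL17B	ENST00000622877.4	201	- 99 (CTCC)3	1
ATP7A	ENST00000343533.9	201	- 27 (GAGG)3	0
DRD2	ENST00000542616.1	207	- 54 (GCCC)3	1
DUX4	ENST00000565211.1	203	- 144 (GGCT)6	1
FAM83G	ENST00000388995.10	202	- 80 (TCTG)3	0
GTF2IRD2B	ENST00000614064.4	206	- 17 (GAAA)3	0
JCAD	ENST00000375377.1	201	- 13 (CCGG)3	0
MCTP2	ENST00000451018.7	203	- 102 (GTTT)3	0
METTL21C	ENST00000267273.6	201	- 69 (CAGT)3	0
OR10G6	ENST00000307002.3	201	- 123 (GATA)13	0
PHYHD1	ENST00000308941.9	201	- 107 (TTTA)3	0
SAMD1	ENST00000269724.5	201	- 75 (CCGC)3	0
TEAD4	ENST00000540314.1	206	- 51 (CTCC)3	1
TRAJ49	ENST00000390488.1	201	- 124 (GCCT)7	0
TRDJ2	ENST00000390475.1	201	- 86 (CCAC)3	0
TRAV38-1	ENST00000390464.2	201	- 109 (CACC)3	0
TRAV7	ENST00000390429.3	201	- 111 (GACA)3	0
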