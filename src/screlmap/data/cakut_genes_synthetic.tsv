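# Curated CAKUT-associated gene set: SYNTHETIC reconstruction.
# Symbols assembled from genes named across the CAKUT genetics literature;
# ensembl_id values are synthetic placeholders (ENSG99...), not real accessions.
hgnc_symbol	ensembl_id	evidence	inheritance
PAX2	ENSG99000000001	Definitive	AD
HNF1B	ENSG99000000002	Moderate	AR
EYA1	ENSG99000000003	Strong	XL
SIX1	ENSG99000000004	Limited	AD/AR
SIX2	ENSG99000000005	Definitive	AD
SIX5	ENSG99000000006	Moderate	AR
SALL1	ENSG99000000007	Strong	XL
SALL4	ENSG99000000008	Limited	AD/AR
GATA3	ENSG99000000009	Definitive	AD
BMP4	ENSG99000000010	Moderate	AR
BMP7	ENSG99000000011	Strong	XL
RET	ENSG99000000012	Limited	AD/AR
GDNF	ENSG99000000013	Definitive	AD
GFRA1	ENSG99000000014	Moderate	AR
WNT4	ENSG99000000015	Strong	XL
WNT9B	ENSG99000000016	Limited	AD/AR
FGF20	ENSG99000000017	Definitive	AD
FGFR1	ENSG99000000018	Moderate	AR
FGFR2	ENSG99000000019	Strong	XL
FRAS1	ENSG99000000020	Limited	AD/AR
FREM1	ENSG99000000021	Definitive	AD
FREM2	ENSG99000000022	Moderate	AR
GRIP1	ENSG99000000023	Strong	XL
ITGA8	ENSG99000000024	Limited	AD/AR
DSTYK	ENSG99000000025	Definitive	AD
TNXB	ENSG99000000026	Moderate	AR
TBX18	ENSG99000000027	Strong	XL
SOX17	ENSG99000000028	Limited	AD/AR
NRIP1	ENSG99000000029	Definitive	AD
CHD1L	ENSG99000000030	Moderate	AR
ROBO1	ENSG99000000031	Strong	XL
ROBO2	ENSG99000000032	Limited	AD/AR
SLIT2	ENSG99000000033	Definitive	AD
SRGAP1	ENSG99000000034	Moderate	AR
UPK3A	ENSG99000000035	Strong	XL
ANOS1	ENSG99000000036	Limited	AD/AR
GREB1L	ENSG99000000037	Definitive	AD
TFAP2A	ENSG99000000038	Moderate	AR
PBX1	ENSG99000000039	Strong	XL
CDC5L	ENSG99000000040	Limited	AD/AR
HPSE2	ENSG99000000041	Definitive	AD
LRIG2	ENSG99000000042	Moderate	AR
CHRM3	ENSG99000000043	Strong	XL
ACE	ENSG99000000044	Limited	AD/AR
AGT	ENSG99000000045	Definitive	AD
AGTR1	ENSG99000000046	Moderate	AR
AGTR2	ENSG99000000047	Strong	XL
REN	ENSG99000000048	Limited	AD/AR
WT1	ENSG99000000049	Definitive	AD
LHX1	ENSG99000000050	Moderate	AR
OSR1	ENSG99000000051	Strong	XL
EMX2	ENSG99000000052	Limited	AD/AR
HOXA11	ENSG99000000053	Definitive	AD
HOXD11	ENSG99000000054	Moderate	AR
FOXC1	ENSG99000000055	Strong	XL
FOXC2	ENSG99000000056	Limited	AD/AR
FOXP1	ENSG99000000057	Definitive	AD
CHRNA3	ENSG99000000058	Moderate	AR
VWA2	ENSG99000000059	Strong	XL
NPNT	ENSG99000000060	Limited	AD/AR
COL4A1	ENSG99000000061	Definitive	AD
BNC2	ENSG99000000062	Moderate	AR
GPC3	ENSG99000000063	Strong	XL
GLI3	ENSG99000000064	Limited	AD/AR
MUC1	ENSG99000000065	Definitive	AD
UMOD	ENSG99000000066	Moderate	AR
NOTCH2	ENSG99000000067	Strong	XL
JAG1	ENSG99000000068	Limited	AD/AR
CRKL	ENSG99000000069	Definitive	AD
BICC1	ENSG99000000070	Moderate	AR
CELSR1	ENSG99000000071	Strong	XL
MYOCD	ENSG99000000072	Limited	AD/AR
TBX6	ENSG99000000073	Definitive	AD
STRA6	ENSG99000000074	Moderate	AR
ITGA3	ENSG99000000075	Strong	XL
GREM1	ENSG99000000076	Limited	AD/AR
ETV3	ENSG99000000077	Definitive	AD
KCNQ1OT1	ENSG99000000078	Moderate	AR
APP	ENSG99000000079	Strong	XL
BCAM	ENSG99000000080	Limited	AD/AR
COL18A1	ENSG99000000081	Definitive	AD
IGFBP7	ENSG99000000082	Moderate	AR
CALD1	ENSG99000000083	Strong	XL
VCAN	ENSG99000000084	Limited	AD/AR
SLIT3	ENSG99000000085	Definitive	AD
SOX11	ENSG99000000086	Moderate	AR
WNT11	ENSG99000000087	Strong	XL
CDKN1C	ENSG99000000088	Limited	AD/AR
TRAP1	ENSG99000000089	Definitive	AD
ETV4	ENSG99000000090	Moderate	AR
SPRY1	ENSG99000000091	Strong	XL
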