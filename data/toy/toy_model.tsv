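#! name=toy_aspm_seed0
#! biomass=BIOMASS
#! product=EX_ap3
#! substrate=EX_glc
id	equation	lb	ub	gpr	subsystem	kind
EX_glc	1 glc[e] <->	-10	1000		Transport/Exchange	exchange
EX_nh4	1 nh4[e] <->	-1000	1000		Transport/Exchange	exchange
EX_pyr	1 pyr[e] ->	0	1000		Transport/Exchange	exchange
EX_co2	1 co2[e] ->	0	1000		Transport/Exchange	exchange
EX_ap3	1 ap3[e] ->	0	1000		Transport/Exchange	exchange
GLCt	1 glc[e] -> 1 glc[c]	0	1000	peg.1106 or peg.1007	Transport/Exchange	transport
NH4t	1 nh4[e] -> 1 nh4[c]	0	1000	peg.1169 or peg.1091	Transport/Exchange	transport
PYRt	1 pyr[c] -> 1 pyr[e]	0	1000	peg.1066 or peg.1160	Transport/Exchange	transport
CO2t	1 co2[c] -> 1 co2[e]	0	1000	peg.1072 or peg.1166	Transport/Exchange	transport
AP3t	1 ap3[c] -> 1 ap3[e]	0	1000	peg.1112	Transport/Exchange	transport
HEX	1 glc[c] -> 1 g6p[c]	0	1000	peg.1180 or peg.1093	Glycolysis/EMP	internal
PGI	1 g6p[c] <-> 1 f6p[c]	-1000	1000	peg.1092 or peg.1172	Glycolysis/EMP	internal
FBA	1 f6p[c] -> 2 g3p[c]	0	1000	peg.1153 or peg.1158	Glycolysis/EMP	internal
STO	1 g6p[c] -> 1 sto[c]	0	1000	peg.1073 or peg.1132	Glycolysis/EMP	internal
DM_sto	1 sto[c] ->	0	1000		Transport/Exchange	exchange
GAPDH	1 g3p[c] -> 1 pep[c]	0	1000	peg.1127 or peg.1055	Glycolysis/EMP	internal
PYK	1 pep[c] -> 1 pyr[c]	0	1000	peg.1143 or peg.1140	Glycolysis/EMP	internal
PDH	1 pyr[c] -> 1 accoa[c] + 1 co2[c]	0	1000	peg.1159 or peg.1181	Glycolysis/EMP	internal
G6PDH	1 g6p[c] -> 1 6pg[c]	0	1000	peg.1001	PPP	internal
GND	1 6pg[c] -> 1 co2[c] + 1 ru5p[c]	0	1000	peg.1118	PPP	internal
RPI	1 ru5p[c] <-> 1 r5p[c]	-1000	1000	peg.1040	PPP	internal
TKT	2 r5p[c] -> 1 f6p[c] + 1 g3p[c]	0	1000	peg.1192	PPP	internal
PRPPS	1 r5p[c] -> 1 prpp[c]	0	1000	peg.1139	Nucleotide	internal
CS	1 accoa[c] + 1 oaa[c] -> 1 cit[c]	0	1000	peg.1154	TCA	internal
ACN	1 cit[c] -> 1 icit[c]	0	1000	peg.1120	TCA	internal
ICDH	1 icit[c] -> 1 akg[c] + 1 co2[c]	0	1000	peg.1069 and peg.1100	TCA	internal
GLUDH	1 akg[c] + 1 nh4[c] -> 1 glu[c]	0	1000	peg.1199	TCA	internal
ANA	1 pep[c] -> 1 oaa[c]	0	1000	peg.1137	TCA	internal
PURS	1 prpp[c] -> 1 imp[c]	0	1000	peg.1164	Nucleotide	internal
NUCS	1 imp[c] -> 1 nuc[c]	0	1000	peg.1061	Nucleotide	internal
ASPTA	1 nh4[c] + 1 oaa[c] -> 1 asp[c]	0	1000	peg.1146	Methionine/SAM	internal
HSD	1 asp[c] -> 1 hse[c]	0	1000	peg.1006	Methionine/SAM	internal
HSK	1 hse[c] -> 1 hcy[c]	0	1000	peg.1124	Methionine/SAM	internal
METS	1 hcy[c] -> 1 met[c]	0	1000	peg.1081	Methionine/SAM	internal
SAMS	1 met[c] -> 1 sam[c]	0	1000	peg.1117	Methionine/SAM	internal
SAHt	1 sah[c] -> 1 sah[e]	0	1000	peg.1090	Transport/Exchange	transport
EX_sah	1 sah[e] ->	0	1000		Transport/Exchange	exchange
UDPG	1 g6p[c] -> 1 udpg[c]	0	1000	peg.1011	Product biosynthesis	internal
AHBAS	1 g3p[c] + 1 pep[c] -> 1 ahba[c]	0	1000	peg.1173	Product biosynthesis	internal
PKS	0.5 accoa[c] + 0.5 ahba[c] + 0.2 udpg[c] -> 1 pre0[c]	0	1000	peg.1014	Product biosynthesis	internal
MT1	1 pre0[c] + 0.333333 sam[c] -> 1 pre1[c] + 0.333333 sah[c]	0	1000	peg.1036	Product biosynthesis	internal
MT2	1 pre1[c] + 0.333333 sam[c] -> 1 pre2[c] + 0.333333 sah[c]	0	1000	peg.1084	Product biosynthesis	internal
MT3	1 pre2[c] + 0.333333 sam[c] -> 1 pre3[c] + 0.333333 sah[c]	0	1000	asm10	Product biosynthesis	internal
TAIL4	1 pre3[c] -> 1 ap3[c]	0	1000	peg.1161	Product biosynthesis	internal
ASM30	1 pre0[c] -> 1 apx[c]	0	1000	asm30	Product biosynthesis	internal
DM_apx	1 apx[c] ->	0	1000		Transport/Exchange	exchange
BIOMASS	0.1 g6p[c] + 0.3 glu[c] + 0.005 met[c] + 0.3 nuc[c] + 0.005 sam[c] ->	0	1000		Biomass	biomass
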