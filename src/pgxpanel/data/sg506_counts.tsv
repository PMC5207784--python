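# Diplotype counts for the 506-subject Singapore cohort (126 Malay,
# 179 Indian, 201 Chinese), with the published phenotype classification.
gene	diplotype	phenotype	Malay	Indian	Chinese
CYP2C9	*1/*1	EM	112	124	189
CYP2C9	*1/*2	IM	0	13	1
CYP2C9	*1/*3	IM	13	36	11
CYP2C9	*2/*3	PM	0	2	0
CYP2C9	*3/*3	PM	1	4	0
CYP2C19	*1/*1	EM	54	39	68
CYP2C19	*1/*2	IM	48	55	84
CYP2C19	*1/*3	IM	6	1	9
CYP2C19	*1/*5	IM	1	0	0
CYP2C19	*1/*8	IM	0	1	0
CYP2C19	*1/*17	UM	5	27	2
CYP2C19	*2/*2	PM	9	26	29
CYP2C19	*2/*3	PM	1	3	4
CYP2C19	*2/*5	PM	1	0	0
CYP2C19	*2/*6	PM	0	0	2
CYP2C19	*2/*17	IM	1	25	2
CYP2C19	*3/*3	PM	0	0	1
CYP2C19	*17/*17	UM	0	1	0
CYP2C19	UND	UND	0	1	0
CYP2D6	*1/*1	EM	13	39	14
CYP2D6	*1/*35	EM	0	2	0
CYP2D6	*1X2/*36	EM	18	2	42
CYP2D6	(*1/*36)X2	EM	3	1	1
CYP2D6	*2A/*9	EM	0	2	0
CYP2D6	*2A/*10	EM	4	6	5
CYP2D6	*2A/*41	EM	1	9	0
CYP2D6	*1/*2A	EM-UM	13	31	8
CYP2D6	*1/*4	IM	2	13	1
CYP2D6	*1/*5	IM	3	4	1
CYP2D6	*1/*7	IM	0	2	0
CYP2D6	*4/*35	IM	0	1	0
CYP2D6	*4X2/*36	IM	1	0	0
CYP2D6	*9/*10	IM	1	0	0
CYP2D6	*10/*10	IM	10	0	2
CYP2D6	*10/*41	IM	3	2	3
CYP2D6	*10X2/*36	IM	14	1	21
CYP2D6	(*10/*36)X2	IM	7	0	23
CYP2D6	*10X2/*36X3	IM	0	0	2
CYP2D6	*10X2/*36XN	IM	0	0	1
CYP2D6	*41/*41	IM	0	1	0
CYP2D6	*36/*41X2	IM	2	0	3
CYP2D6	(*36/*41)X2	IM	0	0	1
CYP2D6	*1/*10	IM-EM	12	4	18
CYP2D6	*1/*41	IM-EM	1	25	6
CYP2D6	*2A/*4	IM-EM	1	2	0
CYP2D6	*2A/*5	IM-EM	0	3	1
CYP2D6	*10X3/*36	IM-EM	0	0	1
CYP2D6	*4/*4	PM	0	2	0
CYP2D6	*4/*5	PM	1	3	0
CYP2D6	*5/*5	PM	0	1	0
CYP2D6	*4/*10	PM-IM	0	2	0
CYP2D6	*4/*41	PM-IM	1	4	0
CYP2D6	*5/*10	PM-IM	1	0	5
CYP2D6	*5/*41	PM-IM	1	2	0
CYP2D6	*10/*36	PM-IM	2	0	8
CYP2D6	*10/*36X2	PM-IM	1	0	3
CYP2D6	*10/*36X3	PM-IM	0	0	1
CYP2D6	*1/*1X2	UM	0	2	1
CYP2D6	*1X3/*36	UM	1	0	2
CYP2D6	*2A/*2A	UM	1	5	2
CYP2D6	*2A/*2AX2	UM	0	1	0
CYP2D6	*2AX2/*36	UM	4	1	16
CYP2D6	(*2A/*36)X2	UM	0	0	1
CYP2D6	UND	UND	4	6	8
CYP3A5	*1/*1	EM	24	28	19
CYP3A5	*1/*3	IM	56	74	69
CYP3A5	*3/*3	PM	46	77	113
VKORC1	*1/*1		9	122	1
VKORC1	*1/*2		55	49	39
VKORC1	*2/*2		62	8	161
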