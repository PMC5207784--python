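# Reference calls for the 10 HapMap validation samples (NA18558 is the
# copy-number calibrator, CN 2/2).
sample_id	coriell_id	exon9_cn	intron2_cn	CYP2D6_no_cn	CYP2D6_cn	CYP2C19	CYP2C9	VKORC1	CYP3A5
H01	NA18592	2	3	*2A/*10	*2AX2/*36	*1/*1	*1/*1	*2/*2	*3/*3
H02	NA18532	2	4	*10/*10	(*10/*36)X2	*1/*1	*1/*1	*2/*2	*3/*3
H03	NA18526	2	4	*1/*10	(*1/*36)X2	*1/*1	*1/*1	*2/*2	*1/*1
H04	NA18610	2	4	*10/*10	(*10/*36)X2	*1/*3	*1/*1	*2/*2	*1/*3
H05	NA18568	2	3	*2A/*10	*2AX2/*36	*1/*1	*1/*1	*2/*2	*3/*3
H06	NA18595	2	3	*1/*10	*1X2/*36	*1/*2	*1/*1	*2/*2	*3/*3
H07	NA18524	2	4	*1/*10	(*1/*36)X2	*1/*2	*1/*3	*2/*2	*1/*3
H08	NA18548	2	4	*10/*10	(*10/*36)X2	*1/*1	*1/*1	*2/*2	*1/*1
H09	NA18534	2	2	*2A/*10	*2A/*10	*1/*2	*1/*1	*2/*2	*3/*3
H10	NA18558	2	2	*1/*10	*1/*10	*1/*2	*1/*1	*2/*2	*3/*3
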