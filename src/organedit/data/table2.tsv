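genome	position	site	location	impact	HPL::At-QED1#6	HPL::At-QED1#1	UBQ::At-QED1#3	UBQ::At-QED1#1	WT
cp	97711	ndhB-291	CDS	S->L	80.3	84.3	88.9	91.8	0
cp	77612	petB_intr-mid	intron	-	40.1	48.0	86.5	87.4	0
cp	31530	trnD-psbM_intergenic	intergenic	-	30.6	31.2	36.3	19.3	0
cp	16335	rps2-203	CDS	S->L	30.2	38.8	72.2	68.7	0
cp	7359	trnQ_3as	intergenic_antisense	-	10.4	13.9	0	32.9	0
cp	128607	ycf1_as	antisense	-	0	5.2	0	0	0
cp	119671	ndhE-96	CDS	S->L	0	0	30.0	44.2	0
cp	33880	psbD_5UTR	UTR5	-	0	0	24.6	37.9	0
cp	78993	petB-petD_intergenic	intergenic	-	0	0	17.6	7.8	0
cp	98961	ndhB-101	CDS	Q->STOP	0	0	16.6	26.6	0
cp	77495	petB_intr	intron	-	0	0	16.2	34.0	0
cp	124713	ndhH-136	CDS	R->STOP	0	0	14.9	14.7	0
cp	64242	ycf10-petA_intergenic	intergenic	-	0	0	13.7	0	0
cp	29881	petN_3UTR	UTR3	-	0	0	10.4	15.0	0
cp	12570	atpF-65	CDS	R->STOP	0	0	8.4	20.3	0
cp	32653	trnE_intergenic-upstream	intergenic	-	0	0	7.7	0	0
cp	93937	ycf2_as2	antisense	-	0	0	6.8	0	0
cp	115955	rpl32-trnL_intergenic-as	intergenic_antisense	-	0	0	5.0	0	0
cp	116881	ccsA-182	CDS	S->L	0	0	0	26.8	0
cp	129614	ycf1-661	CDS	synonymous	0	0	0	14.9	0
cp	114743	rpl32_5UTR	UTR5	-	0	0	0	14.7	0
cp	74956	psbB-27	CDS	T->I	0	0	0	11.8	0
cp	69550	psaJ_5UTR	UTR5	-	0	0	0	11.5	0
cp	83340	rpl14-69	CDS	synonymous	0	0	0	9.7	0
cp	5800	rps16_intr	intron	-	0	0	0	9.5	0
cp	95383	ycf2-2167	CDS	Q->STOP	0	0	0	6.7	0
cp	120048	ndhG-ndhE_intergenic	intergenic	-	0	0	0	5.6	0
cp	90236	ycf2-451	CDS	P->L	0	0	0	5.4	0
cp	90203	ycf2-440	CDS	T->M	0	0	0	5.4	0
cp	90244	ycf2-454	CDS	L->F	0	0	0	5.1	0
cp	90230	ycf2_as	antisense	-	0	0	0	5.1	0
cp	61515	accD_3UTR	UTR3	-	0	0	0	5.0	0
mt	19520	ccmC-83	CDS	H->Y	0	10.6	34.8	46.7	0
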