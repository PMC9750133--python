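site	affinity	HPL::At-QED1#12	HPL::At-QED1#17	UBQ::At-QED1#3	pRB58
ndhB-291	high	88.2	84.3	87.5	0
petB_intr-mid	high	54.9	49.5	70	0
rps2-203	high	52.8	46.1	58.2	0
trnQ_3as	high	14.3	24.5	13.2	0
ndhE-96	low	0	0	3.5	0
psbD_5UTR	low	3.8	3.9	8	0
petB-petD_intergenic	low	0	0	2.1	0
ndhB-101	low	0	0	10.5	0
petB_intr	low	0	0	11.3	0
atpF-65	low	1.8	1.9	1.8	0
ccsA-182	low	0	0	3.2	0
ycf1-661	low	0	0	6.1	0
rpl32_5UTR	low	2.4	5.4	7.3	0
psbB-27	low	0	0	0	0
ndhA-358	control	96.9	87.3	89.1	100
ndhB-50	control	100	100	97.2	100
ndhD-225	control	91.8	86.9	82.7	100
rpoB-184	control	67.6	74	80.1	64.3
rps16_intr	control	96.8	96.8	97.7	98.3
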