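site	affinity	UBQ::Tc-QED1#2	UBQ::Tc-QED1#4	UBQ::Tc-QED1#5	WT
ndhB-291	high	50.3	52.6	66.2	0
petB_intr-mid	high	68.6	68	83.8	0
rps2-203	high	26.2	27.1	48.1	0
trnQ_3as	high	0	3.1	0	0
ndhE-96	low	0	0	3.9	0
psbD_5UTR	low	4.3	2.8	0	0
petB-petD_intergenic	low	0	0	0	0
ndhB-101	low	0	6	0	0
petB_intr	low	5.5	9.9	26.2	0
atpF-65	low	0	0	0	0
ccsA-182	low	0	1.7	16.1	0
ycf1-661	low	0	0	0	0
rpl32_5UTR	low	0	0	0	0
psbB-27	low	0	0	9.3	0
ndhA-358	control	100	100	100	100
ndhB-50	control	100	100	100	100
ndhD-225	control	91.6	97.5	83.9	100
rpoB-184	control	63.3	61.9	58	53
rps16_intr	control	100	96.7	100	100
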