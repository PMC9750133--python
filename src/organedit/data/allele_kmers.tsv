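site	kmer_C	kmer_T
matK-214	TTCTTATATAATTCTCATGTATGTGAATACG	TTCTTATATAATTCTTATGTATGTGAATACG
rpoB-811	TTCGTGTATATATTTCACAGAAACGTGAAAT	TTCGTGTATATATTTTACAGAAACGTGAAAT
ndhB-291	TTCCTTTTTATTTCTCATCAAATGAATGGCA	TTCCTTTTTATTTCTTATCAAATGAATGGCA
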