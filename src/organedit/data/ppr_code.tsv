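variant	mclass	aa2	aa5	aaLast	bases
two_aa	*	-	T	N	A
two_aa	*	-	T	D	G
two_aa	*	-	S	N	A
two_aa	*	-	S	D	G
two_aa	*	-	N	D	U
two_aa	*	-	N	S	C
two_aa	*	-	N	N	CU
two_aa	*	-	V	N	AU
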