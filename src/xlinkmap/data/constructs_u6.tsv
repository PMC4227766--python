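name	length	cleavage_sites	tag	tag_mass_shift
H	721	168	N	2.3
Ha	721	189	N	2.3
A	721	247	N	2.3
B	721	305	N	2.3
C	721	358	N	2.3
D	721	409	N	2.3
De	721	445	N	2.3
dE	721	463	N	2.3
E	721	483	N	2.3
UT	721	358	none	0.0
NT	721	358	N	2.3
CT	721	358	C	5.7
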