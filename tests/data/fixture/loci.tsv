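locus	length	orf_start	orf_end	mito
locus_00000	120	0	120	0
locus_00001	120	0	120	0
locus_00002	120	0	120	0
locus_00003	120	0	120	0
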