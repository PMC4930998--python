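individual	species	locality
Lv_1	Lv	lvA
Lv_2	Lv	lvA
Lv_3	Lv	lvB
Lv_4	Lv	lvC
Lm_1	Lm	lmA
Lm_2	Lm	lmB
Lm_3	Lm	lmC
Lh_1	outgroup	outgroup
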