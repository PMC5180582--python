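pipeline	AA	AB	BB	NN
AA	901	0	2	0
AB	54	404	7	0
BB	0	2	116	0
NN	11	1	2	0
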