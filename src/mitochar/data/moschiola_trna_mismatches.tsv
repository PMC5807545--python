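gene	pair	stem	count
trnF	A-A	AA	1
trnF	A-C	AA	1
trnM	U-U	TPC	2
trnM	A-G	AA	1
trnW	A-C	AC	1
trnK	A-G	AA	1
trnR	A-C	AA	1
trnS1	A-C	AA	1
trnT	U-U	AA	1
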