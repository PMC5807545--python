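species	family	accession
Bos indicus	Bovidae	AF492350
Moschus chrysogaster	Moschidae	JQ608470
Axis axis	Cervidae	NC_020680
Giraffa camelopardalis	Giraffidae	JN632645
Moschiola indica	Tragulidae	KY290452
Hyemoschus aquaticus	Tragulidae	NC_020714
Tragulus kanchil	Tragulidae	NC_020753
Sus scrofa	Suidae	AY574047
Camelus bactrianus	Camelidae	NC_009628
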