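# Side-chain and terminal pKa values by named table.
# columns: table<TAB>group<TAB>pka
emboss	nterm	8.6
emboss	cterm	3.6
emboss	C	8.5
emboss	D	3.9
emboss	E	4.1
emboss	H	6.5
emboss	K	10.8
emboss	R	12.5
emboss	Y	10.1
sillero	nterm	8.2
sillero	cterm	3.2
sillero	C	9.0
sillero	D	4.0
sillero	E	4.5
sillero	H	6.4
sillero	K	10.4
sillero	R	12.0
sillero	Y	10.0
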