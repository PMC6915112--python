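Chr	Position	Ref	Alt	♀6	♂9	ZD10	ZD20	ZD30	ZD40	ZD50	ZD60
Scaffold32	7259	T	A	W	W	W	W	W	W	W	W
Scaffold19	12935	A	G	A	R	A	R	R	R	–	R
Scaffold42	123	C	T	T	T	T	T	T	T	T	T
Scaffold311	1271	T	C	T	C	C	C	C	C	C	C
Scaffold1438	26108	T	G	T	G	T	T	T	K	K	G
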