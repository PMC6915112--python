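class	species	count
Bacteria	Burkholderia multivorans	5
Bacteria	Mixia osmundae	9
Bacteria	Scedosporium apiospermum	1
Fungus	Branchiostoma belcheri	4
Fungus	Saccharomyces cerevisiae	4
Fungus	Naumovozyma dairenensis	3
Rhodophyta	Chondrus crispus	15
Rhodophyta	Furcellaria lumbricalis	2
Rhodophyta	Gracilaria chorda	2
Rhodophyta	Gracilaria gracilis	3
Rhodophyta	Gracilaria vermiculophylla	2
Rhodophyta	Gracilariopsis lemaneiformis	3
Zoology	Mus musculus	1
Zoology	Octodon degus	5
Zoology	Spodoptera frugiperda	9
Unknown	Unknown	6687
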