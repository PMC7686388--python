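microbe	neurotransmitter	direction	ref_label	pmid	level
Bifidobacterium dentium	GABA		DeVadder 2018	29866843	B
Bifidobacterium dentium	GABA		Pokusaeve 2017	27458085	B
Bifidobacterium dentium	GABA		Barrett 2012	22612585	C
Lactobacillus plantarum	Acetylcholine	increase	Stanasze 1997	907345	C
Clostridium	Dopamine		Asano 2012	23064760	B
Clostridium	Norepinephrine		Asano 2012	23064760	B
Escherichia coli	Dopamine		Shishov 2009	19845286	C
Escherichia coli	Norepinephrine		Shishov 2009	19845286	C
Bacillus mycoides	Dopamine		Tsavkelova 2000	10935181	C
Bacillus mycoides	Norepinephrine		Tsavkelova 2000	10935181	C
Bacillus subtilis	Dopamine		Tsavkelova 2000	10935181	C
Bacillus subtilis	Norepinephrine		Tsavkelova 2000	10935181	C
Escherichia coli	Dopamine		Tsavkelova 2000	10935181	C
Escherichia coli	Norepinephrine		Tsavkelova 2000	10935181	C
Proteus vulgaris	Dopamine		Tsavkelova 2000	10935181	C
Proteus vulgaris	Norepinephrine		Tsavkelova 2000	10935181	C
Serratia marcescens	Dopamine		Tsavkelova 2000	10935181	C
Serratia marcescens	Norepinephrine		Tsavkelova 2000	10935181	C
Lactobacillus plantarum	Serotonin	increase	placeholder (uncited)	900000001	E
Lactobacillus plantarum	Dopamine	increase	placeholder (uncited)	900000001	E
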