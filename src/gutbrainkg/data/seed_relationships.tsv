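neurotransmitter	disorder	ref_labels	pmids	levels
GABA	Anxiety disorders	placeholder (uncited)	900001001	E
GABA	Depressive disorder	placeholder (uncited)	900001002	E
Acetylcholine	Depressive disorder	placeholder (uncited)	900001003	E
Acetylcholine	Sleep disorders	placeholder (uncited)	900001004	E
Acetylcholine	Sex behavior disorder	placeholder (uncited)	900001005	E
Acetylcholine	Bipolar disorder	placeholder (uncited)	900001006	E
Acetylcholine	Cognition disorders	placeholder (uncited)	900001007	E
Acetylcholine	Autistic disorder	placeholder (uncited)	900001008	E
Dopamine	Bipolar disorder	placeholder (uncited)	900001009	E
Norepinephrine	Bipolar disorder	placeholder (uncited)	900001010	E
Serotonin	Depressive disorder	placeholder (uncited)	900001011	E
Serotonin	Anxiety disorders	placeholder (uncited)	900001012	E
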