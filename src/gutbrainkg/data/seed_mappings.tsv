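kind	label	cui	mesh_id	kegg_compound	kegg_pathways
neurotransmitter	Serotonin			C00780	
neurotransmitter	Dopamine			C03758	
neurotransmitter	GABA			C00334	
neurotransmitter	Norepinephrine			C00547	
neurotransmitter	Histamine			C00388	
neurotransmitter	Acetylcholine			C01996	
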