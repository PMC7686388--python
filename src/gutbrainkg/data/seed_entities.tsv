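kind	label
neurotransmitter	Serotonin
neurotransmitter	Dopamine
neurotransmitter	GABA
neurotransmitter	Norepinephrine
neurotransmitter	Histamine
neurotransmitter	Acetylcholine
mental_disorder	Anxiety disorders
mental_disorder	Depressive disorder
mental_disorder	Sleep disorders
mental_disorder	Eating disorders
mental_disorder	Sex behavior disorder
mental_disorder	Personality disorder
mental_disorder	Bipolar disorder
mental_disorder	Autistic disorder
mental_disorder	Cognition disorders
mental_disorder	Learning disorders
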