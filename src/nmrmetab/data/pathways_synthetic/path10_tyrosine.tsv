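tyrosine	l-dopa
l-dopa	dopamine
dopamine	norepinephrine
norepinephrine	epinephrine
tyrosine	tyramine
tyrosine	4-hydroxyphenylpyruvate
4-hydroxyphenylpyruvate	homogentisate
homogentisate	fumarate
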