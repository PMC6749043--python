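methionine	s-adenosylmethionine
s-adenosylmethionine	s-adenosylhomocysteine
s-adenosylhomocysteine	homocysteine
homocysteine	methionine
homocysteine	cystathionine
serine	cystathionine
cystathionine	cysteine
cysteine	pyruvate
cysteine	taurine
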