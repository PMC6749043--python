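squalene	lanosterol
lanosterol	zymosterol
zymosterol	desmosterol
desmosterol	cholesterol
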