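aminoacyl-trna	alanine
aminoacyl-trna	asparagine
aminoacyl-trna	aspartate
aminoacyl-trna	glutamate
aminoacyl-trna	glutamine
aminoacyl-trna	glycine
aminoacyl-trna	histidine
aminoacyl-trna	isoleucine
aminoacyl-trna	lysine
aminoacyl-trna	methionine
aminoacyl-trna	serine
aminoacyl-trna	threonine
aminoacyl-trna	tyrosine
aminoacyl-trna	valine
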