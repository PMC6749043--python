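pyruvate	alanine
alanine	glutamate
glutamate	2-oxoglutarate
glutamate	glutamine
glutamate	aspartate
aspartate	oxaloacetate
aspartate	asparagine
aspartate	fumarate
glutamate	gaba
gaba	succinate
2-oxoglutarate	succinate
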