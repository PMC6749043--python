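glutamine	glutamate
glutamate	2-oxoglutarate
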