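shikimate	chorismate
chorismate	prephenate
prephenate	phenylalanine
phenylalanine	tyrosine
chorismate	anthranilate
anthranilate	tryptophan
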