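glucose	glucose-6-phosphate
glucose-6-phosphate	inositol-1-phosphate
inositol-1-phosphate	myo-inositol
myo-inositol	phosphatidylinositol
phosphatidylinositol	inositol-1,4,5-trisphosphate
inositol-1,4,5-trisphosphate	inositol-1,4-bisphosphate
inositol-1,4-bisphosphate	inositol-1-phosphate
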