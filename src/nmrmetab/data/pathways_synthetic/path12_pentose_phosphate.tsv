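glucose-6-phosphate	6-phosphogluconate
6-phosphogluconate	ribulose-5-phosphate
ribulose-5-phosphate	ribose-5-phosphate
ribulose-5-phosphate	xylulose-5-phosphate
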