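threonine	glycine
glycine	serine
serine	pyruvate
3-phosphoglycerate	phosphoserine
phosphoserine	serine
choline	betaine
betaine	dimethylglycine
dimethylglycine	sarcosine
sarcosine	glycine
glycine	guanidinoacetate
guanidinoacetate	creatine
threonine	2-oxobutanoate
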