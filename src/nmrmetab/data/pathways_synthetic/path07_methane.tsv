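methanol	formaldehyde
formaldehyde	formate
formate	carbon-dioxide
serine	formaldehyde
serine	glycine
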