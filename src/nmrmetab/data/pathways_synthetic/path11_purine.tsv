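adenosine	inosine
inosine	hypoxanthine
hypoxanthine	xanthine
xanthine	urate
guanosine	guanine
guanine	xanthine
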