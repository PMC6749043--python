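sphinganine	ceramide
ceramide	sphingosine
ceramide	sphingomyelin
sphingosine	sphingosine-1-phosphate
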