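threonine	2-oxobutanoate
2-oxobutanoate	2-aceto-2-hydroxybutanoate
2-aceto-2-hydroxybutanoate	isoleucine
pyruvate	2-aceto-2-hydroxybutanoate
pyruvate	2-acetolactate
2-acetolactate	2-oxoisovalerate
2-oxoisovalerate	valine
2-oxoisovalerate	leucine
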