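metabolite,protein
tyrosine,TH
tyrosine,TYR
alanine,AGXT2
alanine,ALT
glutamate,ALT
glutamate,KAT
glutamine,KAT
methionine,CBS
methionine,CTH
serine,CBS
serine,CTH
myo-Inositol,PLD2
histidine,HDC
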