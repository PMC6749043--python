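id,name,file
path01,Aminoacyl-tRNA biosynthesis,path01_aminoacyl_trna.tsv
path02,"Alanine, aspartate and glutamate metabolism",path02_ala_asp_glu.tsv
path03,D-Glutamine and D-glutamate metabolism,path03_gln_glu.tsv
path04,Cysteine and methionine metabolism,path04_cys_met.tsv
path05,"Glycine, serine and threonine metabolism",path05_gly_ser_thr.tsv
path06,"Phenylalanine, tyrosine and tryptophan biosynthesis",path06_phe_tyr_trp.tsv
path07,Methane metabolism,path07_methane.tsv
path08,"Valine, leucine and isoleucine biosynthesis",path08_val_leu_ile.tsv
path09,Inositol phosphate metabolism,path09_inositol_phosphate.tsv
path10,Tyrosine metabolism,path10_tyrosine.tsv
path11,Purine metabolism,path11_purine.tsv
path12,Pentose phosphate pathway,path12_pentose_phosphate.tsv
path13,Butanoate metabolism,path13_butanoate.tsv
path14,Sphingolipid metabolism,path14_sphingolipid.tsv
path15,Steroid biosynthesis,path15_steroid.tsv
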