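metabolite,shift_ppm,multiplicity,relative_area,base_level,integration_shift
Isoleucine,0.94,t,0.5,0.6,
Isoleucine,1.01,d,0.5,0.6,
3-aminoisobutyrate,1.23,d,1.0,0.4,
3-Hydroxybutyrate,2.31,m,0.333333,0.8,
3-Hydroxybutyrate,2.41,m,0.333333,0.8,
3-Hydroxybutyrate,4.16,m,0.333334,0.8,
Alanine,1.48,d,1.0,0.8,
Asparagine,2.87,m,0.5,0.4,
Asparagine,2.96,m,0.5,0.4,
Aspartate,2.69,s,1.0,0.5,
Betaine,3.27,s,0.5,0.7,
Betaine,3.91,s,0.5,0.7,
choline,3.2,s,1.0,0.5,
cytidine,6.07,d,1.0,0.3,
formate,8.46,s,1.0,0.3,
Fumarate,6.53,s,1.0,0.2,
glucose,3.42,t,0.166667,5.0,
glucose,3.54,dd,0.166667,5.0,
glucose,3.72,t,0.166667,5.0,
glucose,3.74,m,0.166667,5.0,
glucose,3.84,m,0.166667,5.0,
glucose,5.24,d,0.166665,5.0,
glutamate,2.08,m,0.333333,1.0,
glutamate,2.15,m,0.333333,1.0,
glutamate,2.35,m,0.333334,1.0,
glutamine,2.14,m,0.333333,1.2,
glutamine,2.45,m,0.333333,1.2,
glutamine,3.8,m,0.333334,1.2,
glycerol,3.58,m,0.333333,0.8,
glycerol,3.66,m,0.333333,0.8,
glycerol,3.8,m,0.333334,0.8,
glycine,3.56,s,1.0,0.8,
lactate,1.33,s,0.5,2.5,4.11
lactate,4.11,q,0.5,2.5,4.11
LDL/VLDL,0.89,br,0.333333,3.0,
LDL/VLDL,1.31,br,0.333333,3.0,
LDL/VLDL,1.57,br,0.333334,3.0,
Lipids,2.1,br,0.333333,2.0,
Lipids,2.24,br,0.333333,2.0,
Lipids,5.31,br,0.333334,2.0,
Lysine,1.86,m,0.25,0.7,
Lysine,1.88,m,0.25,0.7,
Lysine,3.03,t,0.25,0.7,
Lysine,3.76,t,0.25,0.7,
methionine,2.14,s,0.5,0.4,
methionine,2.64,t,0.5,0.4,
myo-Inositol,3.28,t,0.333333,0.6,4.07
myo-Inositol,3.63,t,0.333333,0.6,4.07
myo-Inositol,4.07,t,0.333334,0.6,4.07
pyruvate,2.37,s,1.0,0.6,
serine,3.83,m,0.5,0.8,
serine,3.98,m,0.5,0.8,
threonine,4.28,m,1.0,0.7,
"N,N-dimethylglycine",2.93,s,1.0,0.3,
tyrosine,6.89,d,0.5,0.5,
tyrosine,7.19,d,0.5,0.5,
valine,0.99,d,0.333333,0.7,
valine,1.04,d,0.333333,0.7,
valine,2.27,m,0.333334,0.7,
citrate,2.56,d,0.5,0.9,
citrate,2.67,d,0.5,0.9,
creatine,3.04,s,0.5,0.9,3.93
creatine,3.93,s,0.5,0.9,3.93
histidine,3.99,m,0.5,0.4,7.07
histidine,7.07,m,0.5,0.4,7.07
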