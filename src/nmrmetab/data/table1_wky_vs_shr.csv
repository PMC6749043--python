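metabolite,shifts,p,vip,fc
Isoleucine,0.94(t);1.01(d),0.00,1.81,0.82
3-aminoisobutyrate,1.23(d),0.01,1.60,1.15
3-Hydroxybutyrate,2.31(m);2.41(m);4.16(m),0.00,2.01,1.36
Alanine,1.48(d),0.00,2.00,1.18
Asparagine,2.87(m);2.96(m),0.03,1.36,1.22
Aspartate,2.69(s),0.00,2.10,1.40
Betaine,3.27(s);3.91(s),0.00,1.98,0.85
choline,3.20(s),0.00,1.98,3.20
cytidine,6.07(d),0.00,1.77,0.44
formate,8.46(s),0.02,1.41,0.83
Fumarate,6.53(s),0.02,1.37,1.70
glucose,3.42(t);3.54(dd);3.72(t);3.74(m);3.84(m);5.24(d),0.00,2.01,0.78
glutamate,2.08(m);2.15(m);2.35(m),0.00,2.50,1.54
glutamine,2.14(m);2.45(m);3.80(m),0.00,1.82,1.21
glycerol,3.58(m);3.66(m);3.80(m),0.04,1.27,0.87
glycine,3.56(s),0.00,2.06,0.84
lactate,1.33(s);4.11(q),0.00,1.69,1.32
LDL/VLDL,0.89(br);1.31(br);1.57(br),0.01,1.52,0.56
Lipids,2.10(br);2.24(br);5.31(br),0.00,1.71,0.90
Lysine,1.86(m);1.88(m);3.03(t);3.76(t),0.02,1.39,0.74
methionine,2.14(s);2.64(t),0.00,2.08,1.24
myo-Inositol,3.28(t);3.63(t);4.07(t),0.00,2.32,1.25
pyruvate,2.37(s),0.00,2.58,1.45
serine,3.83(m);3.98(m),0.01,1.66,1.13
threonine,4.28(m),0.03,1.35,1.21
"N,N-dimethylglycine",2.93(s),0.00,1.72,0.76
tyrosine,6.89(d);7.19(d),0.00,1.82,1.29
valine,0.99(d);1.04(d);2.27(m),0.047,1.23,1.09
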