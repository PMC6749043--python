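metabolite,shifts,p,vip,fc
Isoleucine,0.94(t);1.01(d),0.01,2.08,0.88
alanine,1.48(d),0.00,2.64,0.71
Asparagine,2.87(m);2.96(m),0.02,1.91,0.88
citrate,2.56(d);2.67(d),0.01,2.14,0.74
creatine,3.04(s);3.93(s),0.01,2.25,0.86
glucose,3.42(t);3.54(dd);3.72(t);3.74(m);3.84(m);5.24(d),0.00,2.40,1.55
glutamate,2.08(m);2.15(m);2.35(m),0.02,1.91,0.88
glutamine,2.14(m);2.45(m);3.80(m),0.02,1.92,0.87
histidine,3.99(m);7.07(m),0.02,1.91,0.76
lactate,1.33(s);4.11(q),0.03,1.77,0.81
LDL/VLDL,0.89(br);1.31(br);1.57(br),0.00,2.49,1.50
Lysine,1.86(m);1.88(m);3.03(t);3.76(t),0.04,1.75,0.85
methionine,2.14(s);2.64(t),0.00,2.56,0.86
myo-Inositol,3.28(t);3.63(t);4.07(t),0.00,2.37,0.88
pyruvate,2.37(s),0.00,2.46,1.24
serine,3.83(m);3.98(m),0.00,2.27,0.89
threonine,4.28(m),0.00,2.41,0.67
"N,N-dimethylglycine",2.93(s),0.00,1.76,0.80
tyrosine,6.89(d);7.19(d),0.00,2.35,0.79
valine,0.99(d);1.04(d);2.27(m),0.01,2.09,0.99
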