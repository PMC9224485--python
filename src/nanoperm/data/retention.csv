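config,group,L_um,Y,particle,D_ef_m2_s,a
F118,HI,55.5,2.30,nanoAg,1.1982e-11,0.5020
F118,HI,55.5,2.30,nanoCu,1.0818e-11,0.6043
F63,HI,57.5,3.31,nanoAg,0.9000e-11,0.3770
F63,HI,57.5,3.31,nanoCu,0.9733e-11,0.5436
F1,HI,49.3,6.18,nanoAg,0.4924e-11,0.2063
F1,HI,49.3,6.18,nanoCu,0.4587e-11,0.2562
F118+F63,HI,113.0,5.62,nanoAg,0.6433e-11,0.2695
F118+F63,HI,113.0,5.62,nanoCu,0.6947e-11,0.3881
F118+F63+F1,HI,162.3,11.79,nanoAg,0.4732e-11,0.1983
F118+F63+F1,HI,162.3,11.79,nanoCu,0.3798e-11,0.2122
F1+F1,HI,98.6,12.35,nanoAg,0.3949e-11,0.1654
F1+F1,HI,98.6,12.35,nanoCu,0.1972e-11,0.1102
F1+F1+F1,HI,147.9,18.53,nanoAg,0.3625e-11,0.1519
F1+F1+F1,HI,147.9,18.53,nanoCu,0.1359e-11,0.0759
F9*,HF,47.9,5.43,nanoAg,0.2308e-11,0.0967
F9*,HF,47.9,5.43,nanoCu,0.1414e-11,0.0790
F9*+F9*,HF,95.9,10.87,nanoAg,0.1911e-11,0.0801
F9*+F9*,HF,95.9,10.87,nanoCu,0.0881e-11,0.0492
F9*+F9*+F9*,HF,143.8,16.30,nanoAg,0.1773e-11,0.0743
F9*+F9*+F9*,HF,143.8,16.30,nanoCu,0.0877e-11,0.0490
F1+F9*+F1,mixed,146.5,17.79,nanoAg,0.1545e-11,0.0647
F1+F9*+F1,mixed,146.5,17.79,nanoCu,0.0445e-11,0.0249
F9*+F1+F9*,mixed,145.2,17.04,nanoAg,0.1259e-11,0.0528
F9*+F1+F9*,mixed,145.2,17.04,nanoCu,0.0220e-11,0.0123
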