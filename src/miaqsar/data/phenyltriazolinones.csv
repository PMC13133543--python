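id,X,Y,R1,R2,ic50_mg_per_L,pic50
1,S,CH,H,H,1.404,5.29
2,S,CH,H,3-CH3,1.315,5.34
3,S,CH,H,3-Br,1.658,5.32
4,S,C,H,5-CH3,1.173,5.39
5,CH,S,H,H,1.818,5.17
6,O,CH,H,H,2.125,5.08
7,S,CH,Cl,H,0.403,5.88
8,S,CH,Cl,3-CH3,0.362,5.95
9,S,CH,Cl,3-Br,0.524,5.87
10,S,C,Cl,5-CH3,0.243,6.12
11,CH,S,Cl,H,0.672,5.66
12,O,CH,Cl,H,0.691,5.62
13,S,CH,CH3,H,2.638,5.03
14,S,CH,CH3,3-CH3,1.987,5.18
15,CH,S,CH3,H,3.042,4.97
16,O,CH,CH3,H,3.412,4.90
17,S,CH,CF3,H,0.058,6.77
18,S,CH,CF3,3-CH3,0.044,6.90
19,S,CH,CF3,3-Br,0.068,6.79
20,S,C,CF3,5-CH3,0.033,7.03
21,O,CH,CF3,H,0.090,6.56
22,S,CH,Br,H,0.815,5.63
23,S,CH,Br,3-CH3,0.785,5.67
24,S,CH,Br,3-Br,0.968,5.65
25,S,C,Br,5-CH3,0.654,5.75
26,CH,S,Br,H,1.118,5.50
27,O,CH,Br,H,1.241,5.43
28,S,CH,F,H,0.136,6.33
29,S,CH,F,3-CH3,0.106,6.46
30,S,CH,F,3-Br,0.167,6.34
31,S,C,F,5-CH3,0.093,6.51
32,CH,S,F,H,0.179,6.21
33,O,CH,F,H,0.245,6.05
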