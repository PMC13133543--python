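id,X,Y,R1,R2,ic50_mg_per_L,pic50
P1,CH,S,F,3-CH3,,
P2,S,CH,CH3,5-CH3,,
P3,CH,S,CH3,3-CH3,,
P4,CH,S,CF3,3-CH3,,
P5,S,CH,F,"3,5-CH3",,
P6,S,CH,CH3,"3,5-CH3",,
P7,S,CH,CF3,"3,5-CH3",,
P8,S,CH,H,"3,5-CH3",,
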