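label,Fdi,Fpi,Ehi,Vi
-OH,210,500,20000,10.0
=CH-,200,0,0,13.5
-CO-,290,770,2000,10.8
-O-,100,400,3000,3.8
=C<,70,0,0,-5.5
benzene_ring_subst,1270,110,0,52.4
-CH2-,270,0,0,16.1
>CH-,80,0,0,-1.0
>N-,20,800,5000,-9.0
-CH3,420,0,0,33.5
-COOH,530,420,10000,28.5
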