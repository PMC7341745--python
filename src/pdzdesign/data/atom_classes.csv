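class,sigma,epsilon,gb_radius,surface_tension
N,3.25,0.170,1.55,-0.038
H,1.00,0.020,1.15,0.000
C,3.75,0.105,1.70,0.012
O,2.96,0.210,1.50,-0.038
O2,2.96,0.210,1.50,-0.038
OH,3.00,0.152,1.55,-0.038
CT1,3.85,0.080,1.90,0.012
CT2,3.90,0.118,1.90,0.012
CT3,3.96,0.160,1.90,0.012
CAR,3.75,0.110,1.85,0.012
S,3.55,0.250,1.80,0.012
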