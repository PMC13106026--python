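# Material compositions by elemental mass fraction plus bulk density.
# water/air follow standard reference compositions; polymer inserts follow
# their stoichiometry; the two bone-equivalent inserts and the epoxy module
# background are literature-style Catphan sensitometry materials.
name,density_g_cc,H,C,N,O,F,Al,Ar,Ca
water,1.000,0.1119,0,0,0.8881,0,0,0,0
air,0.001205,0,0.000124,0.755268,0.231781,0,0,0.012827,0
pmma,1.190,0.0805,0.5998,0,0.3196,0,0,0,0
acrylic,1.180,0.0805,0.5998,0,0.3196,0,0,0,0
aluminum,2.699,0,0,0,0,0,1.0,0,0
pmp,0.833,0.1437,0.8563,0,0,0,0,0,0
ldpe,0.920,0.1437,0.8563,0,0,0,0,0,0
polystyrene,1.050,0.0774,0.9226,0,0,0,0,0,0
delrin,1.410,0.0671,0.4000,0,0.5329,0,0,0,0
teflon,2.160,0,0.2402,0,0,0.7598,0,0,0
bone_20,1.140,0.0665,0.5395,0.0215,0.2506,0,0,0,0.1219
bone_50,1.400,0.0477,0.4163,0.0152,0.3200,0,0,0,0.2008
epoxy_background,1.120,0.0800,0.6000,0.0200,0.3000,0,0,0,0
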