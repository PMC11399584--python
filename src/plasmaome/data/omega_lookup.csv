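carbons,double_bonds,omega_class
12,0,saturated/other
14,0,saturated/other
14,1,saturated/other
16,0,saturated/other
16,1,saturated/other
17,0,saturated/other
18,0,saturated/other
18,1,omega-9
18,2,omega-6
18,3,omega-3
18,4,omega-3
20,0,saturated/other
20,1,omega-9
20,2,omega-6
20,3,omega-6
20,4,omega-6
20,5,omega-3
22,0,saturated/other
22,1,omega-9
22,2,omega-6
22,4,omega-6
22,5,omega-3
22,6,omega-3
24,0,saturated/other
24,1,omega-9
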