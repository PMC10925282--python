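# scale: FreeEnergy
# provenance: free energy of solution in water (Charton & Charton 1982; amino acid index literature)
# letter	value
A	-0.368
C	4.530
D	2.060
E	1.770
F	1.060
G	-0.525
H	0.000
I	0.791
K	0.000
L	1.070
M	0.656
N	0.000
P	-2.240
Q	0.731
R	-1.030
S	-0.524
T	0.000
V	0.401
W	1.600
Y	4.910
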