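# scale: Steric
# provenance: steric parameter (Charton 1981; amino acid index literature)
# letter	value
A	0.52
C	0.62
D	0.76
E	0.68
F	0.70
G	0.00
H	0.70
I	1.02
K	0.68
L	0.98
M	0.78
N	0.76
P	0.36
Q	0.68
R	0.68
S	0.53
T	0.50
V	0.76
W	0.70
Y	0.70
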