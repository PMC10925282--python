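# scale: SideChainMass
# provenance: amino acid side-chain mass table of the standard pseudo amino acid composition definition
# letter	value
A	15.0
C	47.0
D	59.0
E	73.0
F	91.0
G	1.0
H	82.0
I	57.0
K	73.0
L	57.0
M	75.0
N	58.0
P	42.0
Q	72.0
R	101.0
S	31.0
T	45.0
V	43.0
W	130.0
Y	107.0
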