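# scale: ResidueVol
# provenance: residue volume (Bigelow 1967; amino acid index literature)
# letter	value
A	52.6
C	68.3
D	68.4
E	84.7
F	113.9
G	36.3
H	91.9
I	102.0
K	105.1
L	102.0
M	97.7
N	75.7
P	73.6
Q	92.7
R	109.1
S	54.9
T	71.2
V	85.1
W	135.4
Y	116.2
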