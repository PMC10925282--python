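# scale: ResidueASA
# provenance: residue accessible surface area in tripeptide (Chothia 1976; amino acid index literature)
# letter	value
A	115.0
C	135.0
D	150.0
E	190.0
F	210.0
G	75.0
H	195.0
I	175.0
K	200.0
L	170.0
M	185.0
N	160.0
P	145.0
Q	180.0
R	225.0
S	115.0
T	140.0
V	155.0
W	255.0
Y	230.0
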