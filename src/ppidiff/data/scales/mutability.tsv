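# scale: Mutability
# provenance: relative mutability of amino acids (Dayhoff et al. 1978; amino acid index literature)
# letter	value
A	100.0
C	20.0
D	106.0
E	102.0
F	41.0
G	49.0
H	66.0
I	96.0
K	56.0
L	40.0
M	94.0
N	134.0
P	56.0
Q	93.0
R	65.0
S	120.0
T	97.0
V	74.0
W	18.0
Y	41.0
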