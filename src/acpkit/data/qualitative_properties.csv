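# Qualitative (categorical) amino-acid properties used by the Qualc encoding.
# Each amino acid belongs to exactly one category per property.
amino_acid,hydrophobicity,polarity,charge,aromatic_aliphatic
A,Y,N,N,N
C,Y,Y,N,N
D,N,Y,Negative,N
E,N,Y,Negative,N
F,Y,N,N,Aromatic
G,Y,N,N,N
H,Y,Y,Positive,Aromatic
I,Y,N,N,Aliphatic
K,Y,Y,Positive,N
L,Y,N,N,Aliphatic
M,Y,N,N,N
N,N,Y,N,N
P,N,N,N,N
Q,N,Y,N,N
R,N,Y,Positive,N
S,N,Y,N,N
T,Y,Y,N,N
V,Y,N,N,Aliphatic
W,Y,Y,N,Aromatic
Y,Y,Y,N,Aromatic
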