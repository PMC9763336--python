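# Quantitative amino-acid properties used by the Quanc encoding.
# Rows in conventional biochemistry-table order (storage only; encoding
# column order is fixed by the alphabetical BPF index, not by this file).
# pka = 0 marks amino acids without a side-chain acidity coefficient
# (padding value, entering the z-score as a literal 0).
# Proline's isoelectric point is PROVISIONAL (standard reference value;
# see encoders module notes).
amino_acid,molecular_mass,isoelectric_point,pk1,pk2,pka,vdw_volume
G,75.07,6.06,2.34,9.60,0,47.3
A,89.09,6.11,2.34,9.69,0,64.4
V,117.15,6.02,2.32,9.62,0,98.6
L,131.17,6.04,2.36,9.60,0,115.7
I,131.17,6.04,2.36,9.60,0,115.7
F,165.19,5.76,1.83,9.13,0,139.9
W,204.23,5.88,2.83,9.39,0,196.9
Y,181.19,5.63,2.2,9.11,10.07,136.9
D,133.1,2.98,1.88,9.6,3.65,80.1
H,155.16,7.64,1.82,9.17,6,118.9
N,132.12,5.43,2.02,8.80,0,94.6
E,147.13,3.08,2.19,9.67,4.25,97.2
K,146.19,9.47,2.18,8.95,10.53,118.1
Q,146.15,5.65,2.17,9.13,0,111.7
M,149.21,5.71,2.28,9.21,0,120.5
R,174.2,10.76,2.17,9.04,12.48,138.4
S,105.09,5.7,2.21,9.15,0,66.1
T,119.12,5.6,2.09,9.10,0,88.9
C,121.16,5.15,1.96,10.28,8.18,82.2
P,115.13,6.30,1.99,10.60,0,88
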