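# SYNTHETIC stand-in table of per-amino-acid propensities to occur at
# protein-DNA interfaces (PC_DNA, raw values before scaling to [0,1]).
# The published scale this emulates spans 0 to 2.534; the per-residue
# values here are constructed to follow the well-documented enrichment of
# positively charged (R, K) and polar (N, Q, S, T, H) amino acids at DNA
# interfaces and the depletion of acidic and hydrophobic ones. Replace
# this file with the genuine scale for production use.
# one-letter	raw_propensity
A	0.61
R	2.534
N	1.31
D	0.46
C	0.88
Q	1.17
E	0.47
G	1.04
H	1.40
I	0.68
L	0.56
K	2.29
M	0.82
F	0.71
P	0.74
S	1.28
T	1.33
W	0.89
Y	1.19
V	0.60
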