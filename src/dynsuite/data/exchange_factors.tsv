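# Nearest-neighbour side-chain correction factors for amide hydrogen exchange
# (log10 units), following the reference-peptide approach of Bai, Milne,
# Mayne & Englander (1993), as adopted here for D2O exchange near neutral pH.
# lambda: effect of the residue's own side chain on its amide proton.
# rho:    effect of the residue when it precedes the exchanging amide.
# Ionizable residues (D, E, H) are tabulated in the form dominant at pH 7
# (carboxylates ionized, histidine neutral).
res	acid_lambda	acid_rho	base_lambda	base_rho
A	0.00	0.00	0.00	0.00
R	-0.59	-0.32	0.08	0.22
N	-0.58	-0.13	0.49	0.32
D	0.90	0.58	0.10	-0.18
C	-0.54	-0.46	0.62	0.55
G	-0.22	0.22	0.27	0.17
Q	-0.47	-0.27	0.06	0.20
E	-0.90	0.31	-0.11	-0.15
H	0.00	0.00	-0.10	0.14
I	-0.91	-0.59	-0.73	-0.23
L	-0.57	-0.13	-0.58	-0.21
K	-0.56	-0.29	-0.04	0.12
M	-0.64	-0.28	-0.01	0.11
F	-0.52	-0.43	-0.24	0.06
P	0.00	-0.19	0.00	-0.24
S	-0.44	-0.39	0.37	0.30
T	-0.79	-0.47	-0.07	0.20
W	-0.40	-0.44	-0.41	-0.11
Y	-0.41	-0.37	-0.27	0.05
V	-0.74	-0.30	-0.70	-0.14
NT	0.00	-1.32	0.00	1.62
CT	0.96	0.00	-1.80	0.00
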