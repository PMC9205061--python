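# Physicochemical properties of the 20 canonical amino acids, v1.
# Columns: one-letter code; molecular weight of the free amino acid (g/mol);
# pKa of the alpha-COOH group; pKa of the alpha-NH3+ group; pKa of the side
# chain (0 where the side chain is not ionizable); isoelectric point pI;
# hydrophobicity index at pH 2; hydrophobicity index at pH 7.
# Values are the standard published tables: weights and dissociation
# constants from the CRC Handbook of Chemistry and Physics amino-acid
# tables (Lide, ed.), hydrophobicity indices at pH 2 and pH 7 from the
# Monera et al. (1995) J. Pept. Sci. 1:319-329 scale.
code,weight,pka_cooh,pka_nh3,pka_side,pI,hydrophobicity_ph2,hydrophobicity_ph7
A,89.094,2.34,9.69,0,6.00,47,41
R,174.203,2.17,9.04,12.48,10.76,-26,-14
N,132.119,2.02,8.80,0,5.41,-41,-28
D,133.104,1.88,9.60,3.65,2.77,-18,-55
C,121.154,1.96,10.28,8.18,5.07,52,49
Q,146.146,2.17,9.13,0,5.65,-18,-10
E,147.131,2.19,9.67,4.25,3.22,8,-31
G,75.067,2.34,9.60,0,5.97,0,0
H,155.156,1.82,9.17,6.00,7.59,-42,8
I,131.175,2.36,9.60,0,6.02,100,99
L,131.175,2.36,9.60,0,5.98,100,97
K,146.189,2.18,8.95,10.53,9.74,-37,-23
M,149.208,2.28,9.21,0,5.74,74,74
F,165.192,1.83,9.13,0,5.48,92,100
P,115.132,1.99,10.60,0,6.30,-46,-46
S,105.093,2.21,9.15,0,5.68,-7,-5
T,119.119,2.09,9.10,0,5.60,13,13
W,204.228,2.83,9.39,0,5.89,84,97
Y,181.191,2.20,9.11,10.07,5.66,49,63
V,117.148,2.32,9.62,0,5.96,79,76
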