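# Element symbols for the atom-type one-hot block, v1 (44 entries).
# The final entry "X" is the overflow slot for any symbol not listed.
C
N
O
S
F
Si
P
Cl
Br
Mg
Na
Ca
Fe
As
Al
I
B
V
K
Tl
Yb
Sb
Sn
Ag
Pd
Co
Se
Ti
Zn
H
Li
Ge
Cu
Au
Ni
Cd
In
Mn
Zr
Cr
Pt
Hg
Pb
X
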