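# Seed counterion dictionary: common inorganic ions and organic salt
# fragments, one SMILES per line.  Matching is by canonical SMILES after
# standardization, so charged and neutral forms are listed separately
# where both occur in registered salt forms.
#
# --- inorganic cations ---
[Li+]
[Na+]
[K+]
[Rb+]
[Cs+]
[Mg+2]
[Ca+2]
[Sr+2]
[Ba+2]
[Zn+2]
[Al+3]
[Fe+2]
[Fe+3]
[Cu+2]
[Mn+2]
[Bi+3]
[NH4+]
# --- inorganic anions ---
[F-]
[Cl-]
[Br-]
[I-]
[OH-]
O=S(=O)([O-])[O-]
O=S(=O)(O)[O-]
O=S(=O)(O)O
[O-]S(=O)[O-]
O=[N+]([O-])[O-]
O=N[O-]
O=P([O-])([O-])[O-]
O=P(O)(O)[O-]
O=P(O)(O)O
OB(O)O
[O-]C(=O)[O-]
OC(=O)[O-]
O=C=O
[N-]=[N+]=[N-]
C(=N)(N)N
# --- neutral acids left after standardization ---
Cl
Br
I
F
O=S(=O)(O)Cl
# --- organic acid / salt fragments ---
CC(=O)O
CC(=O)[O-]
OC(=O)C(O)C(O)C(=O)O
OC(=O)C(O)C(O)C(=O)[O-]
OC(=O)/C=C\C(=O)O
OC(=O)/C=C/C(=O)O
[O-]C(=O)/C=C\C(=O)O
OC(=O)C(O)CC(=O)O
OC(=O)CC(O)(CC(=O)O)C(=O)O
[O-]C(=O)CC(O)(CC(=O)O)C(=O)O
OC(=O)CCC(=O)O
OC(=O)C(=O)O
OC(=O)CC(=O)O
OC(=O)C(O)c1ccccc1
Cc1ccc(cc1)S(=O)(=O)O
Cc1ccc(cc1)S(=O)(=O)[O-]
CS(=O)(=O)O
CS(=O)(=O)[O-]
OS(=O)(=O)c1ccccc1
OS(=O)(=O)C1CC2CCC1(C)C2(C)C
OCC(O)C(=O)O
OC(=O)CCCCC(=O)O
CCCCCCCCCCCCOS(=O)(=O)O
OC(=O)c1ccccc1O
O=C(O)c1cc2ccccc2c(Cc2c(O)c(C(=O)O)cc3ccccc23)c1O
OC(=O)C(F)(F)F
[O-]C(=O)C(F)(F)F
OC(=O)CO
CC(O)C(=O)O
CC(O)C(=O)[O-]
OCC(=O)O
OC(=O)C=CC(=O)O
# --- simple amine counterions ---
NCCO
OCC(N)(CO)CO
C1CCNCC1
N1CCNCC1
CN(C)C
CCN(CC)CC
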