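# Curated bank of concatenation-safe SMILES fragments, version 1.
C
CC
CCC
CCCC
CCO
CO
CN
CCN
C(C)C
C(C)(C)C
C(=O)O
C(=O)N
C(=O)C
C(=O)OC
CI
CS
CSC
CNC
COC
C=C
C=CC
C#CC
CS(=O)(=O)C
CNC(=O)C
COCC
C1CC1
C1CCC1
C1CCCC1
C1CCCCC1
C1CCNCC1
C1CCOC1
C1CCOCC1
C1CCNC1
C1CCSC1
C1CCCCN1
c1ccccc1
c1ccncc1
c1cccnc1
c1ccoc1
c1ccsc1
c1cc[nH]c1
c1ccc2ccccc2c1
c1ccc(F)cc1
c1ccc(Cl)cc1
c1ccc(O)cc1
c1ccc(N)cc1
c1ccc(C)cc1
O
N
OC
NC(=O)C
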