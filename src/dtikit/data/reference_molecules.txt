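# Synthetic reference molecule set for descriptor CDF normalization,
# version 1: fragment-bank members and seeded pairwise assemblies.
C
C#CC
C#CCC1CCC1
C#CCCC
C#CCCCCC
C#CCCCN
C(=O)C
C(=O)CC1CCCCC1
C(=O)CC1CCOC1
C(=O)CC1CCOCC1
C(=O)CCNC(=O)C
C(=O)Cc1ccc(Cl)cc1
C(=O)Cc1ccc(O)cc1
C(=O)N
C(=O)NC(=O)C
C(=O)NC(=O)N
C(=O)NC(=O)OC
C(=O)NC1CCCCN1
C(=O)NC1CCNCC1
C(=O)NC1CCOC1
C(=O)NO
C(=O)NOC
C(=O)O
C(=O)OC
C(=O)OC(=O)N
C(=O)OC1CCOCC1
C(=O)OCC1CCCCC1
C(=O)OCN
C(=O)OCOC
C(=O)Oc1ccoc1
C(C)(C)C
C(C)(C)CC(=O)OC
C(C)(C)CC1CCOC1
C(C)(C)CCS(=O)(=O)C
C(C)(C)Cc1ccc(N)cc1
C(C)(C)Cc1ccc(O)cc1
C(C)C
C(C)CC
C(C)CC(=O)N
C(C)COC
C(C)Cc1ccc(Cl)cc1
C1CC1
C1CC1C1CCCC1
C1CC1C1CCOCC1
C1CC1C=C
C1CC1CCC
C1CC1CCO
C1CC1CI
C1CC1c1ccncc1
C1CCC1
C1CCC1C=C
C1CCC1CCCC
C1CCC1CNC(=O)C
C1CCC1c1ccc(Cl)cc1
C1CCC1c1ccccc1
C1CCC1c1ccsc1
C1CCCC1
C1CCCC1C#CC
C1CCCC1C(=O)O
C1CCCC1CN
C1CCCC1CS
C1CCCC1NC(=O)C
C1CCCC1c1ccc(N)cc1
C1CCCC1c1ccccc1
C1CCCC1c1ccncc1
C1CCCCC1
C1CCCCC1C1CCC1
C1CCCCC1C1CCOC1
C1CCCCC1CCC
C1CCCCC1CCN
C1CCCCC1COC
C1CCCCC1OC
C1CCCCN1
C1CCCCN1C(=O)OC
C1CCCCN1C(C)C
C1CCCCN1C1CCOC1
C1CCCCN1COC
C1CCCCN1COCC
C1CCNC1
C1CCNC1C(=O)OC
C1CCNC1C(C)(C)C
C1CCNC1C1CCCC1
C1CCNC1C1CCOC1
C1CCNC1CCC
C1CCNC1CN
C1CCNC1c1ccccc1
C1CCNCC1
C1CCNCC1C1CCCCC1
C1CCNCC1CCN
C1CCNCC1CO
C1CCNCC1c1ccc(C)cc1
C1CCNCC1c1cccnc1
C1CCOC1
C1CCOC1C(=O)OC
C1CCOC1C1CCOC1
C1CCOC1CN
C1CCOC1CNC
C1CCOC1CO
C1CCOC1COCC
C1CCOC1CSC
C1CCOC1c1ccc(F)cc1
C1CCOCC1
C1CCOCC1C(C)C
C1CCOCC1C1CCNC1
C1CCOCC1CCCC
C1CCOCC1c1ccc(C)cc1
C1CCOCC1c1cccnc1
C1CCSC1
C1CCSC1C(=O)C
C1CCSC1C(=O)OC
C1CCSC1CNC
C1CCSC1COCC
C1CCSC1CS(=O)(=O)C
C1CCSC1c1ccc(C)cc1
C1CCSC1c1ccoc1
C=C
C=CC
C=CC1CCNCC1
C=CCC
C=CCC(=O)O
C=CCC1CCC1
C=CCC1CCNC1
C=CCC=CC
C=CCCNC(=O)C
C=CCCS
C=CCO
C=CCOC
C=CO
C=Cc1cc[nH]c1
CC
CC(C)C
CCC
CCC1CCNCC1
CCC1CCSC1
CCCC
CCCC1CCSC1
CCCC=C
CCCC=CC
CCCCC
CCCCC1CC1
CCCCC1CCCCC1
CCCCC1CCNCC1
CCCCC=C
CCCCC=CC
CCCCCCO
CCCCN
CCCCNC
CCCCNC(=O)C
CCCCS
CCCCc1ccc(F)cc1
CCCN
CCCS(=O)(=O)C
CCCSC
CCCc1ccc(N)cc1
CCCc1ccncc1
CCN
CCNC1CCCC1
CCNC1CCCCN1
CCNC1CCNCC1
CCNCCCC
CCNCCO
CCNCO
CCNO
CCO
CCOC(=O)N
CCOC(=O)O
CCOC1CCOCC1
CCOC1CCSC1
CCON
CCOc1ccc(O)cc1
CCS
CCc1ccc(C)cc1
CI
CIC(=O)C
CICC
CICS(=O)(=O)C
CICSC
CIc1cc[nH]c1
CIc1ccncc1
CN
CNC
CNC(=O)C
CNC(=O)CCCCC
CNC(=O)COC
CNC(=O)Cc1ccc(Cl)cc1
CNC(=O)Cc1cccnc1
CNC(=O)O
CNC1CCCCC1
CNC=C
CNCC
CNCC(=O)O
CNCC1CC1
CNCC1CCNCC1
CNCCCN
CNCCNC(=O)C
CNCN
CNCNC(=O)C
CNCc1ccoc1
CNNC(=O)C
CNc1ccc(C)cc1
CO
COC
COC1CCC1
COCC
COCC1CCNC1
COCC1CCNCC1
COCC1CCSC1
COCCC(=O)N
COCCC(C)C
COCCC1CCCCC1
COCCC1CCCCN1
COCCC1CCOCC1
COCCCCN
COCCCO
COCCCOC
COCCN
COCCS(=O)(=O)C
COCCc1cc[nH]c1
COCCc1ccc(F)cc1
COCCc1cccnc1
COCN
CONC(=O)C
COO
COOC
CS
CS(=O)(=O)C
CS(=O)(=O)CC1CCCC1
CS(=O)(=O)CC1CCNC1
CS(=O)(=O)CCI
CS(=O)(=O)CCSC
CS(=O)(=O)Cc1ccc(F)cc1
CSC
CSC#CC
CSC(C)(C)C
CSC1CCNCC1
CSC1CCOCC1
CSC=C
CSCC(C)C
CSCCC
CSCCCC
CSCNC
CSCc1ccc(F)cc1
CSCc1ccc(N)cc1
CSCc1ccccc1
CSCc1ccsc1
CSOC
CSc1ccncc1
CSc1ccsc1
Cc1ccc(Cl)cc1
N
NC
NC(=O)C
NC(=O)CC1CC1
NC(=O)N
NC(=O)O
NC(C)(C)C
NC(C)C
NCCC
NCN
O
OC
OC(C)C
OCC(C)(C)C
OCC(C)C
OCC1CCCCN1
OCCCC
OCCOCC
OCI
OCNC(=O)C
ONC(=O)C
Oc1ccc2ccccc2c1
Oc1ccsc1
c1cc[nH]c1
c1cc[nH]c1C(=O)C
c1cc[nH]c1C1CCOC1
c1cc[nH]c1CCC
c1cc[nH]c1CI
c1cc[nH]c1COC
c1cc[nH]c1COCC
c1cc[nH]c1c1cccnc1
c1cc[nH]c1c1ccoc1
c1ccc(C)cc1
c1ccc(C)cc1C(=O)C
c1ccc(C)cc1CI
c1ccc(C)cc1CN
c1ccc(C)cc1CO
c1ccc(C)cc1COCC
c1ccc(C)cc1c1ccc(C)cc1
c1ccc(C)cc1c1ccc(O)cc1
c1ccc(C)cc1c1cccnc1
c1ccc(Cl)cc1
c1ccc(Cl)cc1C(=O)N
c1ccc(Cl)cc1C(=O)OC
c1ccc(Cl)cc1C1CCOC1
c1ccc(Cl)cc1C=C
c1ccc(Cl)cc1C=CC
c1ccc(Cl)cc1c1ccc(C)cc1
c1ccc(Cl)cc1c1ccc(N)cc1
c1ccc(F)cc1
c1ccc(F)cc1N
c1ccc(F)cc1c1ccc(F)cc1
c1ccc(N)cc1
c1ccc(N)cc1C(=O)N
c1ccc(N)cc1CCC
c1ccc(N)cc1CN
c1ccc(N)cc1CNC(=O)C
c1ccc(N)cc1CS
c1ccc(N)cc1c1ccc(F)cc1
c1ccc(O)cc1
c1ccc(O)cc1C1CC1
c1ccc(O)cc1C1CCOC1
c1ccc(O)cc1C=CC
c1ccc(O)cc1c1ccc(N)cc1
c1ccc2ccccc2c1
c1ccc2ccccc2c1C(C)(C)C
c1ccc2ccccc2c1C(C)C
c1ccc2ccccc2c1C=CC
c1ccc2ccccc2c1CNC(=O)C
c1ccc2ccccc2c1NC(=O)C
c1ccc2ccccc2c1c1ccoc1
c1ccccc1
c1ccccc1C(=O)O
c1ccccc1C1CCC1
c1ccccc1C1CCCC1
c1ccccc1C1CCCCC1
c1ccccc1C=CC
c1ccccc1CCN
c1ccccc1CNC(=O)C
c1ccccc1CS(=O)(=O)C
c1ccccc1c1ccc(F)cc1
c1cccnc1
c1cccnc1C1CCCC1
c1cccnc1CCO
c1cccnc1CN
c1cccnc1CO
c1cccnc1OC
c1cccnc1c1ccc(Cl)cc1
c1ccncc1
c1ccncc1C1CC1
c1ccncc1C=CC
c1ccncc1O
c1ccoc1
c1ccoc1COC
c1ccoc1CS
c1ccoc1c1ccoc1
c1ccoc1c1ccsc1
c1ccsc1
c1ccsc1CN
c1ccsc1c1ccsc1
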