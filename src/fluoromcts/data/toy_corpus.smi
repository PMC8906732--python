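# Toy SMILES corpus: small H/C/N/O molecules (canonical form), one per line.
CCO
CCN
CCC
CC=O
CC(=O)O
CC(N)=O
CCOC
CC#N
C=CC=C
C=CC=O
c1ccccc1
c1ccncc1
c1ccoc1
c1cc[nH]c1
Cc1ccccc1
Oc1ccccc1
Nc1ccccc1
COc1ccccc1
CC(C)O
CC(C)=O
C1CCCCC1
C1CCNCC1
C1CCOC1
O=Cc1ccccc1
CC(=O)c1ccccc1
N#Cc1ccccc1
C=Cc1ccccc1
c1ccc2ccccc2c1
c1ccc2[nH]ccc2c1
c1ccc2occc2c1
c1ccc2ncccc2c1
O=c1occc2ccccc12
C=CC=CC=C
CC=CC=CC
CC=CC=O
O=CC=CO
NC=CC=O
C=C(C)C
C=CCO
C=CCN
CNC(C)=O
CN(C)C
CCNCC
CCOCC
OCCO
NCCO
NCCN
O=CCO
CC(O)C=O
COC=O
CCOC(C)=O
c1cnc2[nH]ccc2c1
c1cnc2occc2c1
Cc1ccncc1
Cc1cccnc1
Nc1ccncc1
Oc1ccncc1
Cn1cccc1
Cc1ccc(C)cc1
Oc1ccc(O)cc1
Nc1ccc(N)cc1
O=Cc1ccc(O)cc1
Nc1ccc(C=O)cc1
C=Cc1ccco1
C=Cc1ccncc1
O=Cc1ccco1
O=Cc1cccnc1
C=CC#N
C=CC=CC#N
CC#CC
C#CC=C
c1ccc(-c2ccccc2)cc1
c1ccc(-c2ccncc2)cc1
C(=Cc1ccccc1)c1ccccc1
O=C(O)c1ccccc1
COC(=O)c1ccccc1
NC(=O)c1ccccc1
CC(=O)Nc1ccccc1
CN(C)c1ccccc1
C=CC(=O)O
C=CC(N)=O
C=CC(=O)OC
CC=CC(=O)O
O=CC=CC=O
OC=CC=CO
C1=CCCCC1
C1=CCC=CC1
C1=CCCC=C1
O=C1CCCCC1
O=C1C=CCCC1
O=C1C=CC=CC1
CC1=CC(=O)CC(C)(C)C1
c1ccc2c(c1)ccc1ccccc12
c1ccc2cc3ccccc3cc2c1
Oc1cccc2ccccc12
Nc1cccc2ccccc12
O=c1ccc2ccccc2o1
Cc1cc(=O)oc2ccccc12
O=c1ccc2ccccc2[nH]1
CC(C)(C)C
CC(C)(C)O
CCC(C)C
CC(C)CO
C1CC1
C1CCC1
O=CC1CC1
C1CCCC1
OC1CCCC1
NC1CCCC1
O=C1CCC1
C1COCCN1
C1CNCCN1
C1COCCO1
C1CCC2CCCCC2C1
C=C1CCCCC1
N=Cc1ccccc1
CN=Cc1ccccc1
ON=Cc1ccccc1
N#Cc1ccc(C=O)cc1
O=Cc1ccc(C=O)cc1
C=Cc1ccc(C=C)cc1
Oc1ccc(C=Cc2ccccc2)cc1
COc1ccc(C=O)cc1
c1cnn2cccc2c1
c1ccc2nccnc2c1
c1cnc2ncccc2c1
C1=Cc2cccc3cccc1c23
CC1=CCCCC1
OCC1CCCCC1
OCc1ccccc1
NCc1ccccc1
OCCc1ccccc1
CC(O)c1ccccc1
CC(N)c1ccccc1
O=C(C=Cc1ccccc1)c1ccccc1
CC(=O)C=Cc1ccccc1
O=CC=Cc1ccccc1
N#CC=Cc1ccccc1
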