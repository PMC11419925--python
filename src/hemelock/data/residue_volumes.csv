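residue,volume_A3
GLY,60.1
ALA,88.6
SER,89.0
CYS,108.5
ASP,111.1
PRO,112.7
ASN,114.1
THR,116.1
GLU,138.4
VAL,140.0
GLN,143.8
HIS,153.2
MET,162.9
ILE,166.7
LEU,166.7
LYS,168.6
ARG,173.4
PHE,189.9
TYR,193.6
TRP,227.8
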