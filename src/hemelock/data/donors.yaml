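# Donor dictionary for the heme-propionate interaction census.
#
# Backbone donors are the alpha carbons of every residue (carbon hydrogen
# bonds); sidechain donors are split into polar (N/O), carbon/sulfur, and
# the Arg/Lys charged groups used for salt bridges.  Each donor atom lists
# the bonded heavy atoms usable as the X vertex of the X-D-A angle.
# Edit or replace this file to change the censused donor set.

backbone:
  atom: CA
  antecedents: [N, C, CB]

sidechain_polar:
  SER: {OG: [CB]}
  THR: {OG1: [CB]}
  TYR: {OH: [CZ]}
  ASN: {ND2: [CG]}
  GLN: {NE2: [CD]}
  HIS: {ND1: [CG, CE1], NE2: [CD2, CE1]}
  TRP: {NE1: [CD1, CE2]}
  ARG: {NE: [CD, CZ], NH1: [CZ], NH2: [CZ]}
  LYS: {NZ: [CE]}

# Carbon (and sulfur) sidechain donors: the beta carbon of every residue
# that has one, plus the cysteine thiol.
sidechain_carbon:
  ALA: {CB: [CA]}
  ARG: {CB: [CA, CG]}
  ASN: {CB: [CA, CG]}
  ASP: {CB: [CA, CG]}
  CYS: {CB: [CA, SG], SG: [CB]}
  GLN: {CB: [CA, CG]}
  GLU: {CB: [CA, CG]}
  HIS: {CB: [CA, CG]}
  ILE: {CB: [CA, CG1, CG2]}
  LEU: {CB: [CA, CG]}
  LYS: {CB: [CA, CG]}
  MET: {CB: [CA, CG]}
  PHE: {CB: [CA, CG]}
  PRO: {CB: [CA, CG]}
  SER: {CB: [CA, OG]}
  THR: {CB: [CA, OG1, CG2]}
  TRP: {CB: [CA, CG]}
  TYR: {CB: [CA, CG]}
  VAL: {CB: [CA, CG1, CG2]}

salt_bridge:
  ARG: [NE, NH1, NH2]
  LYS: [NZ]
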