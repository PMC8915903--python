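# Default chemotype definitions for chemical-space profiling.
#
# A documented, editable subset of named structural fragment patterns in
# the style of public chemotype sets, covering the categories used in
# comparative TTC dataset profiling (alcohols, phenols, amines, aromatic
# amines, ketones, heterocycles, organohalides, nitriles, long alkane
# chains, terminal C=C, tert-butyl aromatics, ...).  Users may supply a
# larger definition file in the same format.  Column order in fingerprint
# matrices follows file order.

chemotypes:
  - id: alcohol
    label: aliphatic alcohol
    pattern: "[CX4][OX2H]"
  - id: phenol
    label: phenol
    pattern: "[c][OX2H]"
  - id: aromatic_amine
    label: aromatic amine
    pattern: "[c][NX3;!$([NX3](=O)=O)]"
  - id: amine
    label: aliphatic amine
    pattern: "[CX4][NX3;!$([NX3]C=O);!$([NX3](=O)=O)]"
  - id: ketone
    label: ketone
    pattern: "[#6][CX3](=[OX1])[#6]"
  - id: aldehyde
    label: aldehyde
    pattern: "[CX3H1]=[OX1]"
  - id: carboxylic_acid
    label: carboxylic acid
    pattern: "[CX3](=[OX1])[OX2H]"
  - id: ester
    label: carboxylic ester
    pattern: "[CX3](=[OX1])[OX2][#6]"
  - id: ether
    label: ether
    pattern: "[#6][OX2;!$(OC=O)][#6]"
  - id: amide
    label: amide
    pattern: "[CX3](=[OX1])[NX3]"
  - id: heterocycle
    label: heterocyclic ring
    pattern: "[!#6;!#1;R]"
  - id: aromatic_ring
    label: benzene ring
    pattern: "c1ccccc1"
  - id: aromatic_alkane
    label: alkyl-substituted aromatic
    pattern: "[c][CX4]"
  - id: organohalide
    label: organohalide
    pattern: "[#6][F,Cl,Br,I]"
  - id: nitrile
    label: nitrile
    pattern: "[CX2]#[NX1]"
  - id: nitro
    label: nitro group
    pattern: "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"
  - id: alkane_chain_gt6
    label: alkane chain longer than 6
    pattern: "[CX4][CX4][CX4][CX4][CX4][CX4][CX4]"
  - id: terminal_alkene
    label: carbon-carbon double bond at the molecular terminus
    pattern: "[CX3H2]=[CX3]"
  - id: tert_butyl_aromatic
    label: tert-butyl on an aromatic ring
    pattern: "[c][CX4]([CH3])([CH3])[CH3]"
  - id: thioether
    label: divalent sulfur
    pattern: "[#6][SX2]"
  - id: sulfonyl
    label: sulfonyl group
    pattern: "[#16X4](=[OX1])(=[OX1])"
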