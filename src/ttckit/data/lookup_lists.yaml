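# Lookup lists consulted by the structural-class decision tree.
#
# Membership is tested on the canonical SMILES of the salt-stripped
# largest carbon fragment.  For common_food_components a second, looser
# test also accepts a molecule whose Murcko ring scaffold matches the
# scaffold of a list entry ("structurally closely related").
# Both lists are deliberately minimal defaults and are user-extensible.

normal_body_constituents:
  - name: D-glucose
    smiles: OCC1OC(O)C(O)C(O)C1O
  - name: glycerol
    smiles: OCC(O)CO
  - name: citric acid
    smiles: OC(=O)CC(O)(CC(=O)O)C(=O)O
  - name: L-lactic acid
    smiles: CC(O)C(=O)O
  - name: pyruvic acid
    smiles: CC(=O)C(=O)O
  - name: succinic acid
    smiles: OC(=O)CCC(=O)O
  - name: acetic acid
    smiles: CC(=O)O
  - name: urea
    smiles: NC(N)=O
  - name: glycine
    smiles: NCC(=O)O
  - name: L-alanine
    smiles: CC(N)C(=O)O
  - name: L-glutamic acid
    smiles: NC(CCC(=O)O)C(=O)O
  - name: palmitic acid
    smiles: CCCCCCCCCCCCCCCC(=O)O
  - name: stearic acid
    smiles: CCCCCCCCCCCCCCCCCC(=O)O
  - name: oleic acid
    smiles: CCCCCCCC/C=C\CCCCCCCC(=O)O

common_food_components:
  - name: 2-methylpyrazine
    smiles: Cc1cnccn1
  - name: 2,3-dimethylpyrazine
    smiles: Cc1nccnc1C
  - name: 2,3,5-trimethylpyrazine
    smiles: Cc1cnc(C)c(C)n1
  - name: 2-ethylpyrazine
    smiles: CCc1cnccn1
  - name: furfural
    smiles: O=Cc1ccco1
  - name: furfuryl alcohol
    smiles: OCc1ccco1
  - name: 2-acetylfuran
    smiles: CC(=O)c1ccco1
  - name: maltol
    smiles: CC1=C(O)C(=O)C=CO1
  - name: 2-acetylpyrrole
    smiles: CC(=O)c1ccc[nH]1
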