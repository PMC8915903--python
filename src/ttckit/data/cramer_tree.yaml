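# Structural-class decision tree (classes I / II / III).
#
# A compact, auditable encoding of the classical three-class structural
# decision scheme for oral systemic toxicity: innocuous, efficiently
# metabolized structures fall into Class I; structures that are less
# innocuous but carry no positive indication of toxicity (typically
# simple heteroaromatics common in food) into Class II; everything with
# reactive groups, unusual elements, nitrogenous aromatic substitution or
# uncommon ring systems into Class III.
#
# Each node asks one yes/no question about the salt-stripped largest
# carbon fragment and routes to another node id or to a terminal class
# ("class I" / "class II" / "class III").  Predicates are either named
# built-ins (documented in ttckit.cramer) or SMARTS-list matches; every
# SMARTS list lives in this file so reviewers can audit and amend the
# interpretation of qualitative wording such as "functional groups
# associated with enhanced toxicity".

root: Q1

smarts_sets:
  # Reactive / enhanced-toxicity structural alerts.
  toxicity_alerts:
    epoxide: "[CX4]1[OX2][CX4]1"
    aziridine: "[CX4]1[NX3][CX4]1"
    n_nitroso: "[NX3][NX2]=[OX1]"
    hydrazine: "[NX3][NX3]"
    azo: "[NX2]=[NX2]"
    isocyanate: "[NX2]=[CX2]=[OX1]"
    isothiocyanate: "[NX2]=[CX2]=[SX1]"
    michael_acceptor_enone: "[CX3]=[CX3][CX3]=[OX1]"
    thiocarbonyl: "[#6]=[SX1]"
    thiol: "[SX2H]"
    aliphatic_nitro: "[CX4][N+](=O)[O-]"
    aliphatic_nitro_neutral: "[CX4][NX3](=O)=O"
    quaternary_nitrogen: "[NX4+]"
    peroxide: "[OX2][OX2]"
  # Nitrogenous substitution on an aromatic carbocycle (anilines,
  # nitroaromatics, aromatic azo compounds, aryl hydroxylamines).
  aromatic_nitrogen_alerts:
    aromatic_amine: "[c][NX3;!$([NX3](=O)=O)]"
    aromatic_nitro: "[c][N+](=O)[O-]"
    aromatic_nitro_neutral: "[c][NX3](=O)=O"
    aromatic_azo: "[c][NX2]=[NX2]"
    aryl_hydroxylamine: "[c][NX3][OX2H]"

nodes:
  Q1:
    question: Is the substance a normal constituent of the body or a normal
      intermediary metabolite?
    predicate: {type: lookup, list: normal_body_constituents}
    if_yes: Q2
    if_no: Q3
  Q2:
    question: Does it contain functional groups associated with enhanced
      toxicity?
    predicate: {type: smarts_any, set: toxicity_alerts}
    if_yes: Q3
    if_no: class I
  Q3:
    question: Does it carry a reactive or enhanced-toxicity structural alert
      (epoxide, aziridine, N-nitroso, hydrazine, azo, isocyanate,
      Michael-acceptor enone, thiocarbonyl, thiol, aliphatic nitro,
      quaternary nitrogen, peroxide)?
    predicate: {type: smarts_any, set: toxicity_alerts}
    if_yes: class III
    if_no: Q4
  Q4:
    question: Does it contain elements other than C, H, O, N and divalent
      sulfur?
    predicate: {type: hetero_elements}
    if_yes: Q16
    if_no: Q5
  Q5:
    question: Is it an open-chain (acyclic) substance?
    predicate: {type: acyclic}
    if_yes: Q6
    if_no: Q9
  Q6:
    question: Is it an aliphatic hydrocarbon or a common carbohydrate?
    predicate: {type: hydrocarbon_or_carbohydrate}
    if_yes: class I
    if_no: Q7
  Q7:
    question: Are its functional groups limited to innocuous oxygen
      chemistry (alcohol, aldehyde, ketone, acid, ester, ether, acetal)?
    predicate: {type: heteroatoms_only_oxygen}
    if_yes: Q8
    if_no: Q16
  Q8:
    question: Does it carry three or fewer distinct functional-group types?
    predicate: {type: fg_types_le, n: 3}
    if_yes: class I
    if_no: Q16
  Q9:
    question: Does it contain a heterocyclic ring?
    predicate: {type: has_heterocycle}
    if_yes: Q10
    if_no: Q11
  Q10:
    question: Is it a single 5- or 6-membered N/O/S heterocycle bearing only
      innocuous oxygen-chemistry substituents?
    predicate: {type: simple_heterocycle}
    if_yes: Q16
    if_no: class III
  Q11:
    question: Does it contain an aromatic carbocyclic ring?
    predicate: {type: aromatic_carbocycle}
    if_yes: Q12
    if_no: Q15
  Q12:
    question: Does an aromatic ring bear a nitrogenous substituent (amine,
      nitro, azo, hydroxylamine)?
    predicate: {type: smarts_any, set: aromatic_nitrogen_alerts}
    if_yes: class III
    if_no: Q13
  Q13:
    question: Are ring substituents and side chains limited to hydrocarbon
      and innocuous oxygen chemistry?
    predicate: {type: heteroatoms_only_oxygen}
    if_yes: Q14
    if_no: Q16
  Q14:
    question: Does it contain more than one aromatic ring?
    predicate: {type: multiple_aromatic_rings}
    if_yes: class III
    if_no: class I
  Q15:
    question: Is it a simple alicyclic substance (at most two rings, only
      innocuous oxygen-chemistry substituents)?
    predicate: {type: simple_alicyclic, max_rings: 2}
    if_yes: class I
    if_no: Q16
  Q16:
    question: Is the substance a common component of food or structurally
      closely related to one?
    predicate: {type: lookup, list: common_food_components, scaffold: true}
    if_yes: class II
    if_no: class III
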