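# Structural exclusion rules defining TTC dataset membership.
#
# Categories are tested in the order given; the first match wins and is
# recorded on the substance.  Predicates are element-set tests,
# substructure (SMARTS) tests, or an input-supplied flag (natural toxins
# have no structural definition).
order:
  - inorganic
  - organometal
  - organophosphorus
  - organosilicon
  - steroid
  - azoxy
  - natural_toxin

rules:
  inorganic:
    type: no_carbon
  organometal:
    # Metals and metalloids; Si and P are deliberately absent because they
    # define their own categories below.
    type: elements
    symbols:
      [Li, Be, B, Na, Mg, Al, K, Ca, Sc, Ti, V, Cr, Mn, Fe, Co, Ni, Cu, Zn,
       Ga, Ge, As, Se, Rb, Sr, Y, Zr, Nb, Mo, Ru, Rh, Pd, Ag, Cd, In, Sn,
       Sb, Te, Cs, Ba, La, Hf, Ta, W, Re, Os, Ir, Pt, Au, Hg, Tl, Pb, Bi]
  organophosphorus:
    type: elements
    symbols: [P]
  organosilicon:
    type: elements
    symbols: [Si]
  steroid:
    # Gonane (cyclopenta[a]phenanthrene) ring system, any bond orders.
    type: smarts
    patterns:
      - "[#6]1~[#6]~[#6]~[#6]2~[#6](~[#6]~1)~[#6]~[#6]~[#6]1~[#6]~2~[#6]~[#6]~[#6]2~[#6]~[#6]~[#6]~[#6]~1~2"
  azoxy:
    # N=N+-O- (charged form) and N=N=O (uncharged valence form).
    type: smarts
    patterns:
      - "[#7]=[#7+]-[#8-]"
      - "[#7]=[#7]=[#8]"
  natural_toxin:
    type: flag
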