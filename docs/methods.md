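# Methods

This note documents the models, parameter choices and limitations behind
`ttckit`.  It is the package's own account of its science; all numbers
quoted as outputs are computed by the test suite or the acceptance
script, not asserted by hand.

## Scope and assumptions

The pipeline targets repeated-dose **oral rat** studies (gavage, dietary,
drinking water) with administration periods of 28–179 days and effect
levels expressed as, or convertible to, mg/kg bw/day.  Findings-level
toxicological judgment — which observed effects are adverse, which are
species-specific and not human-relevant (e.g. alpha-2u-globulin
nephropathy in male rats) — is assumed to be already encoded in the input
NO(A)EL/LO(A)EL; the pipeline never re-adjudicates individual findings.
Natural-toxin status is likewise an input flag: no structural definition
of "natural toxin" exists.

## Curation

* **Critical study selection.** Within a substance, studies are ordered
  by reliability rank (ascending; 1 = most reliable), then duration
  (descending), then effect level (ascending).  Residual ties break by
  source enum order and finally input position, so the selection is a
  pure function of the study set.  The reliability scale is deliberately
  an explicit input integer; the package does not infer reliability from
  study metadata.
* **Admissible window.** 28–179 days inclusive.  The narrow reading of
  "1–3 months" would end at ~90 days, but the chronic-adjustment factors
  are defined for two categories, 28–83 and 84–179 days, and the wider
  window is what those categories govern.
* **Exclusion rules** live in `data/exclusion_rules.yaml` and are tested
  in a fixed order (inorganic → organometal → organophosphorus →
  organosilicon → steroid → azoxy → natural toxin); the first match is
  recorded.  Operationalizations: *inorganic* = no carbon atom;
  *organometal* = any atom from a configurable metal/metalloid set
  (excluding Si and P, which have their own categories); *steroid* =
  gonane (cyclopenta[a]phenanthrene) ring system with any bond orders;
  *azoxy* = N=N⁺–O⁻ (plus the uncharged valence form).  Precedence
  between overlapping categories is a package choice; no published
  precedence exists.

## POD adjustment

`POD_adj = effect_level / (f_LOAEL × f_duration)` with `f_LOAEL = 3` when
only a LOAEL is available (1 otherwise) and `f_duration = 6` for 28–83 d,
`3` for 84–179 d.  The category boundaries are applied strictly (83 d →
6, 84 d → 3).  Both factors are recorded on the `AdjustedPOD` so the raw
value is always reconstructable; dose arithmetic is never rounded.

Dose-unit conversion uses configurable intake fractions with defaults
0.08 kg feed/kg bw/day (dietary) and 0.10 L water/kg bw/day (drinking
water) — standard young-rat defaults for subacute studies.  No headline
result depends on them; they only matter for inputs not already in
mg/kg bw/day.

## Structural classification

The classifier is a compact, auditable encoding of the classical
three-class structural decision scheme (Cramer Classes I/II/III) as a
16-node yes/no tree in `data/cramer_tree.yaml`.  It is **not** a clone of
any particular software implementation of that scheme: qualitative
wording such as "functional groups associated with enhanced toxicity" is
operationalized as explicit SMARTS lists kept in the same file, so every
interpretation can be audited and amended, and divergences from other
implementations are reconciled through the expert-override mechanism
(recorded with reason, original tree verdict and concordance flag).

Key behaviors, locked in by tests:

* salts/mixtures are stripped to the largest carbon-containing fragment,
  and classification is invariant to SMILES atom ordering;
* primary and secondary aromatic amines, nitro-/azoaromatics,
  thiocarbonyl compounds, Michael acceptors and other reactive-alert
  structures are Class III;
* unbranched C2–C6 alcohols and their acetate esters, simple
  alkylbenzenes and phenols (including tert-butylphenols), and simple
  alicyclics are Class I;
* simple food-associated heteroaromatics (alkylpyrazines, furfural and
  relatives) are Class II via the common-food-component lookup;
* every assignment carries its full decision path, and replaying the
  path from the root reproduces the class.

Lookup lists (normal body constituents, common food components) ship as
minimal documented defaults and are user-extensible; "structurally
closely related to a common food component" is implemented as Murcko
ring-scaffold identity with a list entry, which is deliberately narrow.

## Threshold statistics

Per class, adjusted PODs are modeled as lognormal.  The location
estimate is the mean of natural logs (so `exp(μ̂)` equals the sample
geometric mean exactly — an identity the tests assert) and the spread is
the sample standard deviation of logs with the n−1 denominator; the
denominator is the conventional choice and is configurable in spirit by
fitting externally and calling `lognormal_p5` directly.  The 5th
percentile uses the fixed constant `z₀.₀₅ = −1.6448536269514722` so
results are bit-reproducible across platforms.

The threshold chain divides the 5th-percentile POD by an uncertainty
factor of 100 (10 interspecies × 10 intraspecies) and scales by a 60 kg
adult body weight.  All chaining is unrounded; rendering rounds the TDI
to 2 significant figures and the per-person value to 3 (rendered pairs
therefore need not multiply exactly — e.g. an unrounded TDI of 1.85
μg/kg bw/day renders as 1.9 but yields a per-person value of 111, not
114).  Classes with fewer than `min_n = 30` substances are rendered
"NA": published datasets decline a Class II threshold at n = 22 without
stating a cutoff, so the default is a package choice, documented and
configurable.

## Chemical-space profiling

Fingerprints are binary presence vectors over an editable set of 21
named SMARTS chemotypes covering the categories used in comparative TTC
profiling (alcohol, phenol, aromatic amine, amine, ketone, heterocycle,
organohalide, nitrile, alkane chain > 6, terminal C=C, tert-butyl
aromatic, …).  Licensed full chemotype sets are not bundled; a user may
supply one in the same YAML format.  PCA runs on the pooled,
column-centered binary matrix; component signs are canonicalized so the
largest-magnitude loading of each component is positive, and requesting
more components than the matrix rank is an error rather than a silent
truncation.

## Synthetic data generator

The generator emulates the statistical structure of a curated
industrial-chemicals TTC dataset: class mixture 0.29 / 0.03 / 0.68,
class-conditional lognormal adjusted-POD distributions with geometric
means 12.5 / 2.6 / 4.7 mg/kg bw/day and log-sds 1.606 / 1.0 / 1.951
(the Class II log-sd is a non-calibrated placeholder — real Class II
samples are too small to constrain it), a 74% / 26% subacute/subchronic
split, 10% LOAEL-only studies, and an excluded-structure fraction of
77/733.  Source labels follow the duration-conditional source mixture of
the published per-source study counts.  Structures come from a
hand-curated exemplar library (67 molecules with expected class or
exclusion category) that the test suite regression-checks against the
classifier, so generator truth labels and tree verdicts cannot drift
apart.

Latents are generated backwards: the target adjusted POD is drawn first
and multiplied by the LOAEL/duration factors assigned to the study, so
the pipeline must invert the factors exactly — a round-trip identity the
tests verify to machine precision.  `fixture_733` fixes the composition
exactly (77 excluded: 10 inorganic, 15 organometal, 16 organophosphorus,
18 organosilicon, 6 steroid, 5 azoxy, 7 natural toxin; 656 retained:
190 / 22 / 444) so curation counts are deterministic.

What the generator does **not** emulate: real structural diversity (it
resamples a small exemplar library), correlations between structure and
POD within a class, dose-spacing artifacts of real studies, or per-source
study counts beyond the duration mixture.  Passing tests therefore
demonstrate correctness of the pipeline's mechanics and estimators under
the stated statistical model, not predictive validity on real chemicals.

## Problem sizes and numerical choices

Recovery checks use 200 replicates at the published class sizes
(n = 444 and 190); estimator-consistency checks use 10,000 draws — sizes
at which Monte-Carlo error of the mean fitted 5th percentile is ≈1%,
comfortably inside the ±5% acceptance band.  Degenerate inputs are
errors, not silent results: fitting needs n ≥ 2 positive values, empty
classes produce `n = 0, reliable = false` entries rather than crashes,
and unparsable structures are rejected at read time with row-level
reasons (never dropped silently).

## Known limitations

* The decision tree is a faithful-but-compact encoding of the classical
  scheme; borderline chemistries (e.g. simple thioethers, styrenes,
  terpenoids) may classify more conservatively than other
  implementations.  The override mechanism is the intended remedy.
* No benchmark-dose modeling; the pipeline is NO(A)EL/LO(A)EL-based.
* No bootstrap/parametric confidence intervals on the 5th percentile.
* Chemotype defaults are a representative subset, not a full licensed
  chemotype dictionary.
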