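# ttckit

Derivation of **Threshold of Toxicological Concern (TTC)** values from
repeated-dose oral toxicity data, as a tested, reusable pipeline.

The TTC approach assigns a generic human exposure threshold to chemicals
with little or no substance-specific toxicity data: substances are sorted
into structural classes (Cramer Classes I, II, III), a point of departure
(POD) distribution is built per class from curated animal studies, and the
5th percentile of each distribution is converted into a tolerable daily
intake.  `ttckit` implements that workflow end to end for subacute and
subchronic oral rat studies — the study type populating regulatory
databases of industrial chemicals — together with a seeded synthetic-data
generator so every stage is testable without any external download.

## Who this is for

Regulatory and computational toxicologists who want a transparent,
scriptable implementation of the TTC derivation chain: dataset curation,
structural exclusion rules, Cramer classification with auditable decision
paths and expert overrides, POD adjustment, lognormal fitting, and
chemical-space profiling.

## The method

1. **Curation.** One *critical study* is kept per substance, selected by
   higher reliability, then longer duration, then lower NO(A)EL — the most
   conservative admissible study.  Substance groups conventionally
   exempted from the TTC approach are removed: inorganics, organic metal
   compounds, organophosphorus and organosilicon compounds, steroids,
   azoxy compounds, and (list-flagged) natural toxins.
2. **POD adjustment.** Each effect level is divided by a LOAEL-to-NOAEL
   factor of 3 when only a LOAEL exists, and by a duration factor of 6
   (subacute, 28–83 d) or 3 (subchronic, 84–179 d):

       POD_adj = NO(A)EL / (f_LOAEL × f_duration)          [mg/kg bw/day]

3. **Cramer classification.** A yes/no structural decision tree (editable
   YAML rules file; SMARTS predicates and lookup lists) assigns Class I
   (presumed low oral toxicity), II (intermediate), or III (no presumption
   of safety), recording the full decision path; expert overrides are
   applied with reason and provenance.
4. **Thresholds.** Per class, adjusted PODs are fitted as lognormal
   (μ̂ = mean of natural logs, σ̂ = n−1 standard deviation of logs) and

       POD_5%  = exp(μ̂ + z_0.05 σ̂),   z_0.05 = −1.6448536…
       TDI     = POD_5% × 1000 / UF            [μg/kg bw/day, UF = 100]
       per-person threshold = TDI × 60 kg      [μg/person/day]

   Classes with fewer than `min_n` substances (default 30) are reported
   as "NA", mirroring standard practice for under-populated Class II.
5. **Chemical space.** Binary chemotype fingerprints (editable SMARTS
   definitions), per-dataset occupancy histograms, and PCA projections of
   the pooled centered fingerprint matrix.

## Worked example

Generate the fixed 733-substance synthetic dataset (77 excluded-group
structures) and run the full derivation:

```bash
ttckit simulate --fixture-733 --seed 1 --out-dir data
ttckit derive --substances data/substances.csv --studies data/studies.csv --out-dir results
```

prints

```
retained 656 / excluded 77
Class I: n=190 TDI=9.5 ug/kg bw/day, 570 ug/person/day
Class II: n=22 TDI=NA ug/kg bw/day, NA ug/person/day
Class III: n=444 TDI=1.7 ug/kg bw/day, 103 ug/person/day
```

Reading: curation removed the 77 excluded-group structures, kept one
critical study for each of the 656 remaining substances, and classified
them 190 / 22 / 444 (29 / 3 / 68 %) into Classes I / II / III.  With this
seed the Class I tolerable daily intake is 9.5 μg/kg bw/day (570
μg/person/day for a 60 kg adult) and Class III is 1.7 μg/kg bw/day (103
μg/person/day); Class II is "NA" because 22 substances are below the
reliability cutoff.  The values move a little from seed to seed because
the synthetic PODs are random draws from the class-conditional lognormal
distributions; `results/ttc_report.json` retains every fitted parameter
at full precision, and `run_manifest.json` records config, seed and input
digests for bit-exact reproduction.

The same steps are available as library calls (`ttckit.fixture_733`,
`ttckit.curate_dataset`, `ttckit.classify_cramer`, `ttckit.pod_table`,
`ttckit.run_ttc_analysis`).

## Layout

```
src/ttckit/            library modules (io, curation, cramer, pod,
                       ttc_stats, chemspace, synthetic, cli)
src/ttckit/data/       editable YAML rules: exclusion rules, decision
                       tree, lookup lists, chemotype definitions
docs/methods.md        model assumptions, parameter choices, limitations
tests/                 pytest suite
```
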