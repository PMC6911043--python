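# ssclip

Splice-site-centric iCLIP cross-link and alternative-splicing analysis.

`ssclip` is for transcriptomics researchers comparing how two isoforms of a
3′-splice-site-binding protein — the motivating case is wild-type vs
S34F-mutant U2AF1 in lung adenocarcinoma cells — engage RNA and reshape
splicing.  From RT-stop cross-link tracks (the single-nucleotide truncation
evidence of iCLIP), a genome, and 3′ splice-site annotations it computes:

* **3′SS occupancy saturation** — a site is occupied when a cross-link
  falls within ±20 nt of the junction; genes sorted by CLIP density
  (stops per 3′SS) are smoothed with a rolling quantile-0.75 over 40-gene
  windows, and the saturation plateau estimates the maximal occupied
  fraction;
* **metagene profiles and binding clusters C1–C10** — per-site binding
  fraction vectors, maximal-binding positions over display window −6..+2
  (sites with ≤10 stops excluded, <10% maxima to C10), and wild-type→mutant
  cluster switches;
* **motif statistics** — hexamer enrichment Z-scores
  `z = (f − μ)/σ` against a resampling null (n = 50 draws of M annotated
  3′SS, M = the number of occupied sites), trinucleotide sliding-window
  profiles over [RT−25, RT+25], positional base-frequency matrices, and a
  mutant/wild-type preferential binding score `log2((f_mut+ε)/(f_wt+ε))`;
* **differential splicing** — ψ = inc/(inc+exc), a Beta(1,1)-binomial
  Bayes factor against the shared-ψ hypothesis, calls at |Δψ| ≥ 0.10,
  BF ≥ 5, ≥ 10 reads; cohort calls on a two-group PSI matrix (Welch t-test
  p < 0.05, |Δmedian ψ| ≥ 0.025), acceptor CAG/TAG co-association, event
  Z-scores at the |Z| > 1.64 tail, and cross-data-set overlap Fisher tests;
* **integration** — 1.5-fold-change binding/expression classes,
  binding–expression concordance (R²), binding-switch × strong-splicing
  co-association, cohort co-occurrence Fisher and hotspot binomial tests.

A first-class synthetic-data generator emulates the statistical structure of
these inputs (condition-specific peak positions one nucleotide apart,
tunable occupied fractions, CAG/TAG-dependent binding weights, coupled PSI
cohorts) so the whole pipeline runs end to end with no external data.  See
`docs/methods.md` for the model and its assumptions.

## Worked example

Run the fully scripted synthetic demonstration (300 genes, ~30 s):

```sh
ssclip demo --seed 3 --out demo_out
```

which prints

```
plateau_wild_type_pct: 86.463
plateau_mutant_pct: 70.806
modal_major_position_wild_type: -5
modal_major_position_mutant: -4
cohort_cag_tag_p: 0.000
binding_expression_r2: 0.001
```

Reading the numbers: the wild-type protein occupies ~86% of 3′ splice
sites at saturating CLIP density while the mutant occupies ~71% — the
generator's configured occupancies, recovered by the saturation analysis.
The most populated major binding cluster sits at display position −5 (the
A of the AG acceptor) for the wild type and −4 (the G) for the mutant: the
single-nucleotide cross-link shift.  The cohort CAG/TAG Fisher p (≈8e-13
here) reflects the planted coupling between acceptor trinucleotide and the
direction of exon-inclusion change, and the binding–expression R² ≈ 0
reflects independently drawn binding and expression fold changes.
`demo_out/` also contains the per-stage TSV tables (saturation curves,
metagene matrix, cluster switches, hexamer Z-scores, splicing calls).

Each stage is equally available on real files via the subcommands
`simulate`, `occupancy`, `metagene`, `clusters`, `motifs`, `splicing`,
`cohort`, and `integrate` (`ssclip --help`), or directly as library
functions (`ssclip.occupancy.saturation_curve`,
`ssclip.motifs.hexamer_zscores`, …).

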