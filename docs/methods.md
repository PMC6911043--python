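# Methods

`ssclip` analyses individual-nucleotide-resolution CLIP (iCLIP) cross-link
evidence around 3′ splice sites (3′SS) and its relationship to alternative
splicing, for a two-condition comparison of an RNA-binding protein — the
motivating case being wild-type vs S34F-mutant U2AF1, the small subunit of
the U2 auxiliary factor that recognises the AG splice-acceptor dinucleotide.
Every analysis stage is driven either by user-supplied standard files
(FASTA, BED6, TSV) or by the package's synthetic-data generator, which
emulates the statistical structure those analyses assume.

## Coordinate model

Internally all positions are 0-based, half-open (BED convention).  Around a
3′SS we use *junction offsets*: 0 is the first exonic nucleotide, −1 the G
of the AG acceptor, −2 the A, −3 the C of CAG (T of TAG).  Minus-strand
sites are reverse-complemented so offsets are always transcript-oriented.
Figure-style *display coordinates* are `internal + display_offset` with
`display_offset = −3`, placing the wild-type main cross-link peak (the A)
at −5 and the mutant peak (the G) at −4.  The offset is configurable
because published metagene axes rarely state their origin; −3 is the value
that makes the package's display labels match the conventional −5/−4 peak
nomenclature.

## Occupancy saturation analysis

A 3′SS is *occupied* when at least one RT stop (reverse-transcription
truncation = deduplicated cross-link event) falls within a closed ±20-nt
window of the junction.  Per gene, CLIP binding density is the total number
of unique RT stops assigned to the gene (each stop goes to the gene whose
nearest 3′SS is closest, within a ±20-nt assignment window by default;
`window_assign=inf` assigns every stop on a shared contig/strand) divided
by the gene's number of 3′SS.  Genes are sorted by density; the density
axis is smoothed with a rolling quantile-0.75 over windows of 40 genes and
each window's occupancy is the mean per-gene occupied fraction.  The
*plateau estimate* is the mean rolling occupancy over the top decile of
windows by density.

Two estimator choices deserve note.  First, window occupancy is aggregated
by the mean, not the 0.75-quantile: per-gene occupied fractions are coarse
binomial-type quantities (a gene has a handful of 3′SS), and an upper
quantile of them is structurally biased upward — with 86% occupancy and
≤ 9 sites per gene the 0.75-quantile is exactly 1 regardless of the true
fraction.  A `occupancy_stat="quantile"` option applies the order statistic
to the fractions for users who want that reading.  Second, the plateau is
defined over top-decile-density windows; any rank-based cut conditions on
observed density and therefore slightly favours genes whose occupied sites
were luckier, which is why the generator controls within-gene occupancy
noise (below).

## Cross-link clusters C1–C10

Per site, counts over a ±25 display-offset span are converted to a fraction
vector.  Sites with ≤ 10 total stops are excluded (the strict "> 10 RT
stops" rule).  If the global argmax lies at display −6..+2 with fraction
≥ 0.10 the site joins major cluster C1..C9 (C_k at position k−7);
otherwise C10.  Argmax ties break toward the most intronic offset (the
rule is otherwise order-dependent and unstated in the source analyses).  A
*cluster switch* is a site in two different major clusters in the two
conditions; sites that are C10/excluded in either condition are dropped
from the majors-only switch table.

## Hexamer and trinucleotide statistics

The null distribution of hexamer frequencies resamples (n = 50, without
replacement) M annotated 3′SS and counts hexamers starting within ±20 of
the junction; M equals the number of occupied 3′SS in the sample being
scored, so null dispersion matches the observed sample size.  Observed
frequencies count hexamers around RT stops near occupied sites, and

    z_h = (f_h − μ_h) / σ_h

per hexamer (σ = 0 ⇒ z missing, never ±∞).  Three counting conventions
matter and are parameters:

* **Anchoring** (`anchor`): the default counts every hexamer *overlapping*
  the 5-bp window centred on the stop.  Restricting to hexamers *starting*
  in that window (`anchor="start"`) makes the set of counted hexamers
  asymmetric around the cross-link: a one-nucleotide peak shift toward the
  junction then halves the number of acceptor-spanning windows per stop,
  which by itself masks genuine acceptor-composition differences between
  conditions.
* **Stop weighting** (`weighted`): each position contributes its unique-RT-
  stop count (every deduplicated cross-link event counts once).  Setting
  `weighted=False` counts covered positions instead.
* **Per-site normalisation** (`per_site_norm`): each site's windows are
  rescaled to unit total weight, matching the site-uniform sampling design
  of the null.  Without it the heavy-tailed coverage distribution lets a
  handful of sites dominate the frequencies and the z-scores are no longer
  calibrated against the resampling null.

Trinucleotide profiles slide a size-3 window over [RT−25, RT+25] and report
per-offset frequencies over the 64 trinucleotides (rows sum to 1; windows
truncated at contig ends are dropped).  The preferential binding score is
`log2((f_mut+ε)/(f_wt+ε))` with ε defaulting to `1/(4·4096·total windows)`;
only hexamers whose pooled frequency reaches the 0.75 support quantile are
ranked, since the extreme ratios of barely-observed hexamers reflect
sampling noise, not preference.  Positional base-frequency matrices
(sequence-logo equivalents) weight each site's acceptor-region sequence by
its total stop count.

## Differential splicing

Two-condition calls use ψ = inclusion/(inclusion+exclusion) per condition
and a Beta(1,1)-binomial Bayes factor comparing independent-ψ against
shared-ψ models, computed by exact log-Beta identities:

    BF = B(i₁+1, e₁+1) B(i₂+1, e₂+1) / B(i₁+i₂+1, e₁+e₂+1)

This is a deliberate, self-contained surrogate for isoform-model Bayes
factors (e.g. MISO's): it honours the same decision thresholds while
remaining exactly testable against numerical integration.  A condition
with zero reads yields BF = 1 (uninformative).  Calls require |Δψ| ≥ 0.10,
BF ≥ 5 and ≥ 10 supporting reads (minimum over the two conditions); the
"strong" tier for binding integration uses BF ≥ 10.  No multiple-testing
correction is applied anywhere — raw p-values are reported.

Cohort (two-group PSI-matrix) calls use Welch's t-test per event plus an
absolute group-median ψ difference ≥ 0.025 at p < 0.05; events with fewer
than two non-missing values in a group are skipped.  The CAG/TAG
co-association test builds a 2×2 Fisher table of acceptor trinucleotide ×
sign of the median difference over called events.  Cross-data-set overlap
converts each non-reference sample's ψ to a Z-score against the reference
group (sd with ddof = 1; ≥ 2 reference values and sd > 0 required), pools
event×sample pairs beyond |Z| > 1.64 (the 0.05 normal tail) and crosses
them with the reference inclusion direction in a Fisher test.

## Integration statistics

Gene-level binding and expression are classified by a 1.5-fold-change rule
with pseudocounts (1 count for CLIP tallies, 0.1 abundance units for
expression) so zeros classify as neutral.  Concordance reports the
per-direction intersection counts and the OLS R² between the two log₂
ratios.  Binding–splicing co-association is a Fisher test of strong
splicing × cluster switch over events mapped to switch-table sites.
Cohort co-occurrence and hotspot tests are exact Fisher and two-sided
binomial (minimum-likelihood convention) respectively.

## The synthetic-data generator

The generator produces one contig per gene with `sites_per_gene = 10` 3′SS
(intron 200 nt / exon 150 nt), acceptor trinucleotides drawn from
{CAG: 0.55, TAG: 0.30, AAG: 0.10, other: 0.05}, a 15-nt polypyrimidine
tract (C 0.35 / T 0.45 / A 0.10 / G 0.10) upstream of each acceptor, and
random flanking sequence, on randomly mixed strands.

RT stops per condition follow:

* occupancy π = 0.86 (wild-type) / 0.70 (mutant), multiplied per site by
  trinucleotide binding multipliers (mutant: CAG 2.0, TAG 0.5) and
  renormalised — capping at 1 with water-filling — so the marginal
  occupied fraction equals π exactly;
* per-gene coverage ~ LogNormal(sd of log = 2.5), shared by both
  conditions as a transcript-abundance proxy; stop totals per occupied
  site are negative-binomial (mean 40 × coverage, dispersion 0.3);
* stop offsets from the condition's peak profile in display coordinates —
  wild-type {−5: 0.6, −12: 0.2, +1: 0.1, background 0.1}, mutant
  {−4: 0.72, −12: 0.12, +1: 0.06, background 0.1} (main peak shifted one
  nucleotide, flanks preserved at reduced relative amplitude) — with
  background uniform over ±50 nt;
* unoccupied sites receive only Poisson(0.05) background stops.

Two variance-control choices make the saturation plateau identifiable by
the rolling-window procedure.  Occupied sites are drawn by systematic
probability-proportional-to-size sampling within each gene (every site
keeps its marginal probability, but the per-gene occupied count is fixed
at its expectation up to the fractional remainder), and acceptor categories
are allocated systematically per gene (every gene matches the global
composition up to rounding).  With independent per-site draws, ranking
genes by observed CLIP density selects genes with luckier occupancy and
biases the plateau upward by several points — a caveat that applies to the
real analysis as well; the generator removes the noise source rather than
pretending the estimator is unbiased under it.

PSI cohorts use two groups (125 "mutant", 175 "wild-type" samples, the
TCGA LUAD split), a Beta(2, 2) baseline ψ per event, an affected fraction
of 0.2 with |Δψ| = 0.3, and a sign coupled to the linked acceptor
(P(+|CAG) = 0.5 + c/2, P(+|TAG) = 0.5 − c/2, coupling c = 0.8).
Per-sample ψ values are binomial read-sampling estimates at Poisson depth
100 with 5% missingness; matching two-condition inclusion/exclusion counts
are drawn at the same depth.  Gene quantification tables use log-normal
expression, CLIP counts proportional to expression, and independent
planted binding/expression fold-change subsets (2.5-fold; 15%/8% binding,
10%/5% expression) so binding and expression ratios are uncorrelated.

All streams derive from a single seed plus a stable label hash per
component, so outputs are byte-identical given a seed and insensitive to
generation order.

### What the generator does not emulate

Real iCLIP features outside its scope: non-uniform background tracking
sequence composition and structure, cross-link-site sequence bias (UV
cross-linking prefers uridines), overlapping genes and shared 3′SS,
alternative 3′SS annotations at single loci, replicate structure, and
mapping artifacts.  Passing tests therefore demonstrate the correctness
and calibration of the estimators under the stated statistical model, not
robustness to those real-data complications.

## Numerical choices

Fisher tests delegate to `scipy.stats.fisher_exact` and are verified
exhaustively against hypergeometric enumeration for all 2×2 tables with
total ≤ 40; degenerate tables (a zero margin) report p = 1 with a warning.
The Bayes factor is computed in log space via `betaln`.  Z-scores with a
reference sd ≤ 1e−9 are reported missing (the tolerance absorbs float
noise on tied ψ values).  Rolling quantiles use pandas' linear
interpolation.  Hexamer counting uses base-4 integer codes; windows
containing N are dropped.  Problem sizes in the test and acceptance runs —
2,000 genes × 5 seeds for occupancy recovery, 1,000 sites for cluster
modes, 500 genes for motif directionality — are the package's chosen
defaults for stable estimates at interactive runtimes.

## Known limitations

* The plateau estimator remains weakly upward-biased on data with
  independent per-site occupancy (see above); on such data treat the
  plateau as an upper estimate.
* The Beta-binomial Bayes factor is not MISO's isoform-aware quantity;
  when MISO output is supplied, its Bayes factors should be used directly.
* The hexamer null resamples annotated 3′SS windows only; it does not
  model binding away from splice sites.
* `cohort_cag_tag_test` counts events once (not event×sample pairs); the
  overlap test pools pairs, following the respective procedures' wording.
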