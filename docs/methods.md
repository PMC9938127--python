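# Methods

## The problem

More than 90% of somatic mutations in tumors fall outside protein-coding
sequence, yet few non-coding variants (NCVs) have been established as cancer
drivers.  `tfabt` implements a TF-aware burden test (TFA-BT): instead of
asking whether a promoter is mutated more often than comparable regions, it
asks whether the NCVs observed in a promoter alter the binding sites of one
particular transcription factor more often than the promoter's own
mutational background predicts.  Using the promoter itself as background
removes the need to model regional covariates (replication timing,
chromatin state, local trinucleotide composition) explicitly — they cancel
inside the promoter.

## PWM scoring and score thresholds

Binding specificity is modeled by position weight matrices (PWMs).  A
candidate site `s` of length `n` scores

    F(s, M) = sum_i log( M[s_i, i] / b[s_i] )

with `b` the background base composition.  Conventions, all configurable:

- **Log base**: natural log.  The score-difference cutoffs of calling
  schemes 2 and 3 (2 and 3) are applied in the same units, so the base is a
  global choice and must not be mixed.
- **Pseudocount**: 1e-4 added to every probability, rows renormalized.
  Public matrix collections contain exact zeros and the score must stay
  finite.
- **Background**: uniform 0.25 per base.
- **Variant scoring**: for a genomic position, all `2n-1` n-mers overlapping
  the position on each strand are scored and the maximum over the `4n-2`
  oriented windows is the site score.  Windows containing N are skipped;
  ties prefer the forward strand, then the leftmost offset.

A score is "significant" for a PWM when it reaches the score threshold at
p-value `alpha = 1e-4` under the background model.  The threshold is exact,
not sampled: per-position log-odds are rounded to a granularity grid
(default 1e-3 score units) and the full distribution of the discretized
score under the background is obtained by dynamic programming (the exact
tail construction used by TFM-pvalue-style algorithms).  The grid threshold
is the smallest grid score with tail probability <= alpha; the reported
threshold is then the smallest *achievable real* score whose discretized
value reaches the grid threshold, found with a min-plus version of the same
dynamic program.  Guarantees therefore hold at the granularity resolution;
the suite checks agreement with exhaustive 4^n enumeration for n <= 8.
A PWM whose score distribution has no tail below alpha (e.g. a uniform
matrix) gets threshold +inf and can never produce calls.

## Promoters

Promoters are windows from 2000 bp upstream to 250 bp downstream of each
protein-coding transcript's TSS, oriented by strand.  Windows of
alternative TSSs of one gene are merged so a recurrent NCV is counted once;
promoters of distinct genes are kept separate even when they overlap (an
NCV inside two genes' promoters contributes an event to each).  CDS
intervals from the same annotation are subtracted — coding positions never
enter the burden test.  Coordinates are 0-based half-open internally and in
BED output; variant records use 1-based VCF convention, converted only at
I/O boundaries.

## Altered-TFBS catalog and calling schemes

For every promoter position, every alternate base, and every PWM, the
reference and alternate best-site scores are compared under three schemes:

1. exactly one allele passes the threshold;
2. at least one allele passes and |score difference| > 2;
3. at least one allele passes and |score difference| > 3.

The direction is `gain` when the alternate allele scores higher, `loss`
otherwise.  The difference in schemes 2–3 uses best-site scores (each
allele's maximum over its own windows), since only best-site scores are
stored in the catalog.  The score-difference cutoffs can be re-derived from
ChIP-seq allelic-imbalance data with `variants.benchmark_schemes`, which
grids the cutoff from 0 to 7, treats loci with binomial p < 0.01 on >= 10
reads as imbalanced, requires the predicted direction to match the read
imbalance (a loss puts more reads on the reference allele), and ranks
candidates by F-value.  Only cells producing a call under some scheme are
stored (sparse catalog), and construction is deterministic and vectorized:
changing the center base shifts an overlapping window's score by a single
column's log-odds difference, so no window is rescored.

## The burden test

For a promoter B (length L, after merging and CDS subtraction) and PWM A,
under the null the number of promoter NCVs altering A in one direction is
Binomial(n, p): n is the number of NCV events in B across patients
(recurrent NCVs count once per tumor), and

    p = sum_{i=1..L, j} F(B_i, M_j) * C(A, B_i, M_j)

where C is the catalog indicator for the tested direction and scheme, and F
is the cohort's substitution-frequency spectrum evaluated at each
(position, alternate base) cell and renormalized to sum to 1 over the
promoter's cells — making p the probability that a single random promoter
NCV alters A.  The spectrum is estimated from the cohort's own mutations;
the default context model is the 12 base-substitution classes, with a
96-class pyrimidine-centric trinucleotide model available by flag.

P-values are exact upper binomial tails.  Within each (cohort, scheme) run,
Benjamini–Hochberg correction is applied over the family of **all testable
triples** — every (promoter, PWM, direction) with p > 0 among promoters
with at least one cohort NCV — with unobserved triples entering at p = 1.
Restricting the family to triples with observed altering events (k >= 1)
was tried first and rejected: it conditions the family on the outcome,
shrinks the correction ~100-fold at this fixture scale, and produced
spurious triple-scheme calls in ~6% of null cohorts; with the full family
the null false-call rate drops below the 5%-of-seeds criterion while
planted drivers (5 excess events among 30) are still recovered with
sensitivity ~1.  Gain and loss are separate hypotheses corrected together;
a variant may be significant in both directions via different PWMs.

A (promoter, PWM, direction) association is reported only when q < 0.01
under **all three schemes independently**, and the emitted driver-NCV calls
are the observed cohort NCVs in that promoter whose catalog record supports
that direction, with per-scheme support flags and recurrence counts.
Cohorts default to one per cancer type plus a pan-cancer pool.

Mutational-process attribution is consumed, not inferred: a variant is
assigned a signature only when that signature's provided probability
exceeds 0.5 (strict).

Overlap between validated variant sets (e.g. expression-modulating vs
binding-modulating) is quantified with percentages of either set, fold
enrichment over the hypergeometric expectation K·n/N, and an upper-tail
hypergeometric p-value.

## Cofactor-recruitment microarray analytics

Probe fluorescence is standardized against background probes in log space:
`z = (log v − mean(log bg)) / sd(log bg)`.  For each variant locus the
reference/alternate comparison spans 6 probe sequences (3 registers × 2
orientations), 5 replicates per allele per sequence.  Each sequence is
tested with an equal-variance two-sided Student's t-test (5 vs 5, 8 df);
the six p-values are combined with Fisher's method (−2 Σ ln p against
chi-square with 12 df); no further per-locus correction is applied beyond
the aggregate cutoff — the enumerated criteria are taken as the complete
rule.  The effect size Δz is the difference of allele mean z-scores over
all 30 probes each.  A locus passes an experiment when max allele z > 2,
|Δz| > 2 and aggregate p < 1e-3, and is a binding-modulating variant
(bmVar) only when it passes both replicate experiments.  The three joint
criteria are deliberately conservative; in the null simulation the bmVar
rate is ~0.

For motif construction, the seed probe is the (register, orientation) cell
with the largest |t| in the initial screen (ties: forward before reverse,
register 0 before −5 before +5), using whichever allele binds more
strongly.  From the seed z-score and the 3×26 single-variant probe
z-scores, the Δz matrix subtracts the per-position median of the four
values (rows median-center to 0 by construction), and the position
probability matrix is a row-wise softmax `exp(βz)/Σ exp(βz)` with

    β = 4            z_seed < 0
    β = 4 − z_seed/2 0 <= z_seed <= 6
    β = 1            z_seed > 6

continuous at both joints.  Positions missing a variant probe are excluded
from motif output.  Motifs are written in MEME minimal format; Δz matrices
as TSV.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
real genomes:

- **Genome/annotation**: one random chromosome (41% GC), 50 protein-coding
  genes alternating strands at 5 kb spacing, CDS placed so it overlaps the
  next gene's upstream window (exercising CDS subtraction).  Exact or
  one-mismatch consensus sites of chosen PWMs are written into chosen
  promoters at recorded positions; exact sites support loss drivers,
  one-mismatch sites gain drivers.
- **PWMs**: 20 random length-8 matrices with consensus probability 0.9 —
  specific enough that at alpha = 1e-4 essentially only the consensus
  passes, as for a high-information real motif.
- **Cohort**: 30 donors, 30 NCV events per promoter, substitution spectrum
  loosely patterned on solid-tumor somatic spectra (transitions elevated,
  C>T dominant).  Background events are drawn cell-by-cell with probability
  proportional to the spectrum — exactly the null the burden test models,
  so p-value calibration is testable.  Planted drivers add events drawn
  only from catalog cells altering the target (PWM, direction) under all
  three schemes.
- **Probe tables**: log-normal background (log-mean 7, log-sd 0.8), 5
  replicates per cell with replicate noise 0.5 z-units, base signal z = 3,
  planted allele effects of 3 z-units; single-variant sets around an
  ETS-like GGAA-core 26-mer with an additive energy model so the motif
  pipeline can recover the planted consensus.

All draws flow from one seed, forked per component via stable hashes, so
identical configs give byte-identical outputs and components do not perturb
each other.  What passing these fixtures does *not* show: robustness to
mis-specified mutational spectra (signature heterogeneity between patients),
promoter covariates that differ *within* a promoter, mapping artifacts, or
subclonal/multi-nucleotide mutation processes — real cohorts violate the
generator's iid assumptions to varying degrees.

## Problem sizes and numerical choices

The shipped calibration suites use 50 promoters × 20 PWMs × 100 cohort
seeds for the burden test and 1100 loci (100 planted) for the microarray
criteria; these sizes give stable Monte-Carlo estimates of the rates being
checked while keeping the default test run short.  Threshold granularity
1e-3 bounds discretization error at n·5e-4 score units per site.  Binomial
and hypergeometric tails come from scipy; BH from statsmodels; interval
algebra from pyranges; annotation parsing via gffutils; FASTA access via
pyfaidx.  Degenerate inputs are defined, not accidental: empty cohorts
return empty results with a warning, uniform PWMs produce empty catalogs,
all-N windows propagate an undefined-score marker, and zero p-values in
Fisher combination are clamped to the smallest positive float with a
warning.

## Known limitations

- Only promoters are modeled; enhancers and other distal elements are out
  of scope.
- Only single-nucleotide variants are tested; multi-nucleotide and indel
  events are excluded.
- The genome-wide precomputed variant-effect database of the original
  large-cohort analysis is replaced by on-demand catalog construction for
  supplied regions; results are identical per position, only the scale
  differs.
- Heterozygous-site discovery for allelic-imbalance calibration is not
  performed; the module consumes tabulated allele counts.
- Signature probabilities are consumed, never inferred.
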