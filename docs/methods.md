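# Methods

## The mapping problem

Seed-plant chloroplast genomes are effectively non-recombining, so a set
of plastomes differing in inheritance strength carries its entire
polymorphism as a single linkage block.  Any locus fixed in a weak
lineage will correlate with weakness whether or not it is causal.  The
pipeline therefore treats window-wise divergence–phenotype correlation
as a *ranking* of candidate loci, offers phylogenetic generalized least
squares (PGLS) to discount correlation explained by relatedness alone,
and keeps the phenotype's direction convention attached to every output
rather than ever flipping signs silently.

## Window counting

Coordinates are 1-based inclusive on the ungapped reference; BED I/O
converts to and from 0-based half-open at the boundary.  One copy of the
large inverted repeat is excised (`strip_inverted_repeat`) before
windowing so duplicated sequence is not counted twice.  The window grid
uses full windows only: with reference length L, window size w and step
s the grid holds ⌊(L−w)/s⌋+1 windows starting at 1, 1+s, 1+2s, ….  A
truncated terminal window is deliberately not emitted; the closed form
is asserted by property tests.

Changes are counted per alignment column, not per mutational event: an
n-bp indel contributes n.  Substitution columns, deletion columns (gap
in the sample) and insertion columns (gap in the reference) each count
one; insertion columns are assigned to the reference position
immediately 5′ of the insertion run, which keeps windows defined purely
on reference coordinates (insertions before the first reference base
belong to no window).  An IUPAC ambiguity code counts as a change only
when its base set shares no base with the reference column — a
conservative divergence measure.  Event-based counting (an indel as one
event regardless of length) is a plausible alternative reading of
"total count of nucleotide changes"; column counting was chosen because
it is deterministic, matches "total sequence divergence", and makes the
generator/counter consistency check exact.

Adjacent windows with identical count vectors are collapsed into one row
before correlation, shrinking the multiple-testing family without
discarding information; the collapse map allows exact reconstruction.

## Correlation mapping

Per (collapsed) window, Pearson r and Spearman ρ are computed between
the count vector and the phenotype.  Pearson p-values use the two-sided
t approximation with n−2 df.  Spearman uses mid-ranks for ties; for
n ≤ 8 samples the p-value is the exact permutation tail over all n!
phenotype orderings, otherwise the t approximation.  Windows whose
count vector has zero variance are flagged undefined and excluded from
the Benjamini–Hochberg family (m is reduced accordingly).  BH is applied
separately per metric, since the two tracks are reported side by side.
BH adjustment is delegated to statsmodels and checked against the
step-up construction by an independent oracle in the tests.

PGLS regresses phenotype on window counts by GLS with tip covariance
C[i,j] = shared root-to-MRCA branch length under Brownian motion,
computed from a user-supplied newick tree (dendropy).  An optional
Pagel's λ scales the off-diagonals; λ is fixed by the caller, not
optimized — the simplest standard model is the default because nothing
in the study design constrains a richer one.  Estimation whitens by the
Cholesky factor and uses a two-sided Wald t test with n−2 df; a singular
covariance (zero-length cherry) is reported with the offending tip
pair.  On a star tree with equal depths the covariance is proportional
to identity and PGLS reproduces OLS to numerical precision (tested to
1e-10).

"Top window" language in the tests means the smallest *raw* p among
BH-significant windows: the BH step-up is a running minimum, so many
windows share the same adjusted q and the q value alone cannot rank
them.

## Inheritance-strength classification

The number of classes is estimated by PAM (BUILD + SWAP, Euclidean
distance, deterministic) over k = 2..10, scoring each k by average
silhouette width and taking the argmax — the documented default
criterion of the partitioning-around-medoids k-estimation procedure the
field uses.  Final assignment uses Euclidean k-means with 100 seeded
restarts (best within-cluster sum of squares kept; scikit-learn's Lloyd
implementation).  Transmission frequencies from different cross series
share percent units and are clustered unscaled by default; a
standardization flag exists.  Classes are relabelled 1..k by ascending
center mean with a `strong_direction` switch, because which end of the
frequency scale is "strong" depends on which parent carried the white
tester plastome.  A user may force k (stability across seeds can be
judged with `swap_rate`, the minimal label-permutation disagreement
fraction via Hungarian matching), but the package never auto-selects k
on grounds other than the silhouette.

## Crossing and assay statistics

Percent biparental inheritance is 100·Σvariegated/Σtotal, per season and
season-pooled (the pooled value is the total-count-weighted mean of
per-season percentages).  Lines are compared to the reference line by
Fisher's exact test on the season-summed 2×2 table, two-sided by the
point-probability method, reporting the sample odds ratio; sidedness is
a documented choice since significance stars alone do not fix it.
Kruskal–Wallis (tie-corrected, χ² p on k−1 df) serves as the omnibus
test for paternal-plastome fractions; the post-hoc procedure is pairwise
two-sided Mann–Whitney against the reference with BH adjustment — a
documented choice where none is prescribed.  All-identical data return
H = 0, p = 1 rather than an error.

ACCase activity: technical-replicate dpm totals are divided by the
incubation time (20 min default), averaged, the minus-acetyl-CoA control
rate subtracted, and the net rate divided by the chloroplast count
(chloroplasts/ml = 10·c̄/4·10⁻⁶ from the counting-chamber average c̄).
Averaging precedes control subtraction; with a single control rate the
order does not change the result.  Relative activities are per
experiment versus the reference line, combined by a two-tailed paired t
test against 1 across experiments and BH-adjusted over lines;
zero-variance ratio sets are flagged NaN rather than given p = 0.

## Lipid-based prediction

Normalization: per series and lipid, levels are log-transformed and the
median over that series' inheritance-class-1 samples subtracted, making
class 1 the common zero across series; normalizing twice is rejected by
a flag.  Series are merged on the lipid intersection (complete data in
every series), with dropped lipids reported.

The response is the ordinal inheritance class 1–5 treated as numeric
Gaussian.  Each of 100 runs holds out all replicates of two randomly
drawn genotypes; on the training genotypes the L1 penalty is chosen by
inner 10-fold CV at the 1-SE rule (largest penalty whose mean CV error
is within one standard error of the minimum); predictors are z-scored
within the training split (as the reference GLM implementation does
internally) and coefficients are reported back on the input scale.  cvR
is the Pearson correlation of actual versus predicted strength over the
pooled held-out replicate samples — pooling, because a correlation over
two genotype means would be degenerate (±1); runs whose held-out actuals
are constant get cvR = NaN and are kept, flagged.

avgW is the mean of absolute per-run coefficients (a config switch
provides the absolute-mean alternative, since the two readings of
"average absolute weight" differ); a lipid is predictive when its avgW
strictly exceeds one sample standard deviation (ddof = 1) of the avgW
vector.  Lipid-class enrichment among predictive lipids uses two-sided
Fisher's exact tests per class with no multiple-testing correction (raw
p and odds ratios are the reported quantities).

## Synthetic data

The generators emit exactly the formats the consumers read, with
ground-truth manifests, and are bit-reproducible given a seed.

Plastome sets: a random ancestor (default 20 kb for tests; the real
genome is ~140 kb ex one IR) is seeded with homopolymer runs (~2 per kb,
8–14 bp) and four 36-bp tandem-repeat loci (9-bp, i.e. in-frame, motifs
× 4 units).  Samples evolve along a random bifurcating tree (sequential
random joins, exponential branch lengths, mean 0.3): SNPs are Poisson
(5·10⁻⁴ per bp per unit branch), 1-bp slippage indels occur at
homopolymer runs, and 1–2-unit in-frame indels at repeat loci, with the
causal locus's indel rate elevated 3-fold so that copy-number variance
exists to map.  The phenotype is β·(changed columns in the causal
locus) summed over causal loci plus Gaussian noise with SD = 0.5× the
signal SD by default — the noise level at which planted-locus recovery
is specified.  Because the simulation knows column homology, the true
alignment is emitted directly (MSA computation is out of scope); the
ancestor is included as the unmutated reference row.  The generator's
per-locus planted divergence is asserted equal to `count_changes` over
the locus, tying generator and counter together.  What this generator
does *not* emulate: codon/rate-heterogeneity substitution models,
alignment error, heteroplasmy — so passing recovery tests show the
statistics behave as designed on clean alignments, not that real
alignment artefacts are handled.

Crosses: variegated counts are Binomial(n_total, rate) per season —
the sampling model behind the percent-biparental statistics (default
200–300 seedlings × 3 seasons, as in the crossing design).

Lipidome: 16 genotypes with classes cycling 1..5, 5 replicates, 3
series, 184 lipids of which 102 are measured in every series (the rest
drop out of at least one), log-levels = baseline + series offset +
β·class + N(0, 0.5), with 8 planted predictive lipids at |β| = 1 and
alternating sign.  Every genotype appears in every series, which
guarantees per-series class-1 centering anchors; the real design's
uneven probe allocation is not emulated.

## Problem sizes and numerical choices

Tests and the acceptance script use the 20-kb / 14-sample plastome
simulation (1901 windows), 20 recovery and 50 null-calibration
replicates, 200 Brownian PGLS replicates on 16 tips, 100 silhouette
selection replicates, and 100-run LASSO pipelines on the
240-sample × 102-lipid merged matrix — sizes chosen so the whole suite
completes in a few minutes on one CPU while keeping the Monte-Carlo
acceptance margins comfortable.  Oracle comparisons use 1e-10–1e-12
absolute tolerance; correlation p-values are clipped to (tiny, 1];
k-means ties and PAM swaps break deterministically; permutation
p-values for small-n Spearman are exact, not sampled.

## Known limitations

* Window counting is column-based; an event-based counter would give
  smaller counts at long indels and is not provided.
* PGLS assumes pure Brownian covariance unless the caller fixes λ; no
  ML estimation of λ, and no alternative covariance families.
* The variant-set practice of overriding the data-driven k on
  interpretability grounds is supported only as an explicit user-forced
  k.
* Enrichment tests on small predictive sets are underpowered; the
  package reports raw p and OR without correction, mirroring how such
  tables are usually read.
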