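# Methods

This note documents the models, statistics, parameter defaults and design
choices behind `aneuhic`, and states what the synthetic benchmarks do and
do not demonstrate.

## Coordinate and matrix conventions

All genomic coordinates are 0-based half-open (BED convention). A
`ChromSizes` fixes chromosome order; bins tile each chromosome at a fixed
resolution (`bin = floor(position / resolution)`), the last bin of a
chromosome may be short. Contact matrices are dense, symmetric and
nonnegative; the "total" of a map counts each unordered bin pair (and each
diagonal pixel) once. Weighted pixel values are `counts[i,j]·w_i·w_j`;
masked bins carry NaN weights and are excluded from every mean.

## Subsampling

Karyotypes are compared at equal sequencing depth. `subsample_to_depth`
draws contacts without replacement — a multivariate hypergeometric over
pixels — which matches the semantics of subsampling reads and conserves
the requested total exactly; requesting the full total returns the
identical map (this is what makes the degenerate trisomy-equals-normal run
exactly null). A multinomial (with-replacement) mode exists behind a flag
for speed on huge maps.

## Balancing (iterative correction)

`balance` implements plain iterative correction with three pixel-selection
modes: genome-wide, cis-only, trans-only. Each iteration divides weights by
the square root of the rescaled weighted marginal; the damped (square-root)
update is used because the full division step can enter period-2
oscillations when the marginal system decouples into independent blocks
(cis-only balancing decouples per chromosome). Convergence is declared when
the coefficient of variation of weighted marginals over unmasked bins drops
below `tol` (default 1e-5, `max_iter` 500); non-convergence is recorded in
`balance_info` and warned about, never silent.

Low-coverage filtering masks bins with zero raw marginal and, by default,
bins whose log marginal falls more than 5 MADs below the median **after
rescaling each chromosome's marginals by that chromosome's median**. The
per-chromosome rescaling matters: chromosomes legitimately differ in
overall trans affinity, and a global MAD rule would mask whole
low-affinity chromosomes rather than genuinely dead bins.

Trans-only balancing has a useful exactness property exploited throughout:
a per-chromosome multiplicative dosage (the 1.5× trisomy factor) is a
diagonal row/column scaling of the trans matrix and is therefore removed
exactly by iterative correction. Comparisons of balanced trans matrices are
consequently insensitive to the raw dosage of the trisomic chromosome,
which is why the trisomic chromosome is analyzed like any other.

## Expected cis curve

`expected_cis` averages pixel values per diagonal offset (s ≥ 1 bin),
pooling numerators and denominators across chromosomes. Raw counts are the
default input; balanced values and log-binned aggregation (geometric bins,
ratio 1.25, diagonal means weighted by pair counts) are options, since the
appropriate combination depends on downstream use and conventions differ
between studies.

## Interchromosomal cluster comparison

The trans contact matrix holds, per chromosome pair, the mean weighted
pixel value over unmasked bin pairs. Fold changes are elementwise
trisomy/normal ratios, missing where either operand is 0 or missing. The
default classification is the human one (small = chr16–chr22, large =
chr1–chr15 + chrX, chrY/chrM excluded); the synthetic genome supplies its
own by chromosome length. Each unordered pair contributes one fold change
to its group (small–small, large–large, small–large). Groups are tested
against 1.0 with a two-sided Wilcoxon signed-rank test and against each
other with two-sided Mann–Whitney U — exact null distribution when both
samples are ≤ 8 and tie-free, normal approximation with tie correction
otherwise.

## Chromosome entourage statistics

For focal chromosome *c*, the FCCF profile pairs its normal trans
frequencies with its trisomy/normal fold changes across all non-excluded
partners (≥ 3 required; partners with missing values drop from both
vectors). Spearman's r uses mid-ranks; its two-sided p-value is computed by
full permutation enumeration for n ≤ 9 partners and by the t approximation
otherwise. A constant vector has no rank variance, so r is reported missing.

"Dispersion" of a profile is the sample variance (ddof = 1) of the FCCF
vector — the simplest moment-based spread; an IQR alternative would be less
sensitive to single-partner outliers but the variance matches the intent of
flagging *any* large partner change.

The stochasticity threshold is the third quartile — linear-interpolation
(type-7) quantile — of dispersions pooled from all pairwise comparisons of
normal samples, all chromosomes together (a per-chromosome baseline is
available as an option). Classification: p < α (default 0.05, no
multiple-testing correction — the ranking display carries significance
flags instead) with r > 0 → *enforced*, r < 0 → *reversed*; otherwise
dispersion above the baseline threshold → *stochastic*, else *unchanged*.
Without ≥ 2 normal samples no baseline exists and the stochastic category
is unreachable (the pipeline warns).

Entourage changes are relational: if chromosome A's contacts with B change,
then B's profile has changed too. Under plans that perturb several
chromosomes, unperturbed chromosomes therefore legitimately classify as
stochastic; recovery benchmarks score only the perturbed chromosomes
against their planned category.

## Local compaction

`R_i` = (cis contacts of bin i within ± `window` of i) / (all cis contacts
of bin i), computed per row with cumulative sums. The window is two-sided
(±1 Mb default, so ±20 bins at 50 kb) as the natural local-density reading.
The diagonal pixel is included in both sums: short-range artifacts are
shared between the compared samples and largely cancel in the fold change.
Raw counts are the default since the ratio is self-normalized per bin;
cis-weighted mode is a flag. R is invariant to global rescaling of the
matrix.

Region calling thresholds the per-bin fold change of R at fixed defaults
0.78 (DOWN) and 1.23 (UP); a percentile mode (5th/85th of the observed
fold-change distribution, applied literally and therefore asymmetric) can
recompute them. Candidate bins merge per direction when their genomic gap
is ≤ `min_dist` (50 kb = one bin), so runs may bridge a single
non-candidate or missing bin; missing bins inside a run contribute their
length to the gap distance. Single-bin clusters are discarded. A region's
`mean_fc` averages only its member candidate bins. Because merging is
distance-based, the *spans* of opposite-direction regions can interleave
through gap bins even though no bin is ever a candidate for both
directions.

Note a structural attenuation: multiplying near-diagonal pixels by a factor
*e* changes R to `e·N/(D+(e−1)·N)`, i.e. the realized fold change of R is
`e/(1+(e−1)R)`, which approaches *e* only when R ≪ 1. On human-scale
chromosomes (≥ 100 Mb) with a 1 Mb window R is naturally small; the
synthetic compaction benchmark reproduces this regime at reduced scale (60
Mb chromosomes with a shallower decay exponent, giving R ≈ 0.13–0.2) so
that injected ×1.4 / ×0.7 effects land clearly outside the 1.23 / 0.78
thresholds.

## Overlap and enrichment

Overlap fractions merge the annotation first, so they are invariant to how
an annotation is split into abutting pieces. Intersection counting treats
every gene body separately (nested and overlapping genes each count;
strand ignored). The shuffle test relocates each region uniformly at random
— by default anywhere in the genome with chromosomes weighted by length
among those long enough, optionally within its own chromosome — preserving
lengths and rejecting placements where shuffled regions overlap each other.
Assembly gaps are not modeled. Empirical p-values use the add-one rule,
`p = (1 + #{null ≥ obs}) / (n + 1)`, so `p·(n+1)` is an integer and p is
never 0; enrichment and depletion are reported symmetrically. Housekeeping
genes are the same code path with a different input BED.

## Synthetic model

Expected cis rate at bin offset s: `magnitude·(s+1)^(−α)` (the +1 keeps the
diagonal finite), times a compartment boost (default 1.3) when both bins
share the A/B label, times any injected compaction effect. Expected trans
rate per pair: a symmetric affinity matrix — base rate with lognormal
per-pair heterogeneity (sd 0.35) and a ×1.8 boost for small–small pairs,
encoding the small-chromosome contact cluster — times donor jitter, CE fold
and trisomy dosage. The rate matrix is rescaled to the target depth
(default 5×10⁶ contacts) and pixel counts are independent Poisson draws on
the upper triangle, mirrored; negative-binomial over-dispersion is a flag.

The affinity heterogeneity is what gives each chromosome "close" and
"distal" partners, i.e. a structured entourage for the CE statistic to
correlate against.

*Trisomy* multiplies the trisomic chromosome's cis block and trans rows by
1.5 — bulk Hi-C cannot separate homolog copies, so an explicit third
homolog would add nothing observable. *CE perturbations* draw one fold
factor per (focal, partner): for enforced/reversed chromosomes a Gaussian
copula against the focal chromosome's baseline affinities with Pearson
ρ_p = 2·sin(π·ρ_s/6) so the rank correlation targets ρ_s (default 0.8),
exponentiated at amplitude 0.3 (lognormal sd); stochastic chromosomes get
independent lognormal factors (amplitude 0.5). The realized pair fold is
the product of both chromosomes' factors. *Compaction injections* multiply
cis pixels with both ends inside the region, or one end inside and
separation ≤ 1 Mb — the same pixel set the ratio R reads — so the realized
fold of R approximates the injected effect up to the attenuation discussed
above.

*Donor jitter*: each normal donor receives an independent lognormal
per-pair trans perturbation (sd 0.05); the trisomy map reuses its matched
control's jitter, mirroring comparisons within one genetic background.
Baseline normal-vs-normal comparisons thus carry inter-donor variability in
their dispersions while the trisomy-vs-matched-control comparison does not
— this separation is what makes the Q3 dispersion threshold informative
rather than an arbitrary 75% false-positive line.

The toy genome defaults to 10 chromosomes of 2.5–20 Mb at 50 kb bins, with
compartment segments ~1.5 Mb, cLADs placed inside B segments at a requested
coverage, and gene density anti-correlated with cLAD coverage (gene-poor
chromosomes are lamina-rich). All sampling is deterministic per seed, with
child seeds derived through `SeedSequence`.

## Benchmark problem sizes

Chromosome-level benchmarks (entourage recovery, cluster-contrast power)
use a 14-chromosome genome (4–16 Mb) at 200 kb bins — the statistics are
computed on chromosome-pair means, so coarse bins lose nothing. Entourage
recovery runs 100 simulated studies (2 enforced + 2 reversed + 2 stochastic
chromosomes each, 2 normal donors); compaction recovery runs 20 studies on
a 2 × 60 Mb genome at 50 kb with α = 0.5 and 20 injected regions of
150–500 kb; shuffle calibration uses 200 null replicates × 200 shuffles;
balancing convergence uses random positive 300-bin maps. With these sizes
the whole validation suite completes in a few minutes on one CPU.

## What passing benchmarks do and do not show

The generator produces Poisson (optionally NB) counts around a
block-structured rate model. It does not emulate TADs, loops, replication
timing, sex-chromosome dosage compensation, mappability/assembly gaps,
translocations, or distance-dependent trans structure. Recovery rates
therefore demonstrate the correctness and statistical calibration of the
estimators under the stated model, not their power on any particular real
dataset, where effect sizes, depths and artifact structure differ.

## Known limitations

- Dense matrices: genome-wide human maps at 50 kb (~60k bins) would need
  ~30 GB; the package targets desk-scale analyses and synthetic studies.
  A sparse backend would be the natural extension.
- The exact-permutation Spearman p is enumerated only for n ≤ 9 partners;
  above that the t approximation is used.
- The shuffle test conditions on the observed region set; it does not model
  spatial autocorrelation of region placement beyond length preservation.
- Percentile-mode compaction thresholds are applied literally to the
  two-sided fold-change distribution (5th and 85th percentiles), which is
  asymmetric by construction.
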