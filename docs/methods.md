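# Methods

This note records the models, parameter choices, numerical conventions and
known limitations of the package, in the order the analyses run.

## Coordinates and gene representation

Internally all coordinates are 0-based half-open; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted only at the parsing/writing
boundary. A gene's representative coding sequence is the longest
transcript's CDS (segments concatenated in genomic order, reverse-
complemented for minus-strand genes). A gene's *position* for every spatial
statistic is the integer midpoint of its span: the midpoint is
strand-symmetric, whereas gene start or CDS start would systematically
shift plus- and minus-strand genes in opposite directions. Soft-masked
bases are uppercased on load; N is tolerated in chromosome sequence but
rejected inside CDS.

## CpG_o/e

CpG_o/e = f_CpG/(f_C·f_G) with mononucleotide frequencies over the L
unambiguous ACGT positions and the dinucleotide frequency over the valid
overlapping windows (L−1 for a clean sequence). Windows or positions
touching a non-ACGT character are excluded from numerator and denominator
alike. Ratios with f_C·f_G = 0 are flagged undefined and excluded (not
zero-filled) from all summaries, with a logged warning. Percentages are
reported to one decimal, rounding half away from zero (66.25% → 66.3%,
the convention needed so 53/80 prints as 66.3%). Tail sets take the
floor(q·n) lowest/highest defined ratios with ties broken by gene id.
"Unimodality" of the distribution is reported descriptively as the mode
count of a Scott's-rule Gaussian KDE on a fixed 512-point grid; no formal
dip test is performed, and the mode count should be read as descriptive
only.

## Term enrichment

Upper-tail hypergeometric p-values, P(X ≥ k) for X ~ Hypergeom(N, K, n),
tested only for terms with ≥ 1 study hit, Benjamini–Hochberg adjusted
(Bonferroni available). Terms are opaque identifiers; no ontology-graph
propagation. The significance cutoff, where one is needed, defaults to
q < 0.05 and is exposed as a parameter.

## Spatial clustering

Spacings are consecutive-midpoint differences within each chromosome,
pooled across chromosomes; telomere-to-first-gene distances are excluded
and zero spacings (tied midpoints) are kept. Three KS null conventions are
provided because "spacings vs a uniform distribution" is ambiguous:

* **uniform-spacing** (default): one-sample KS of the pooled spacings
  against Uniform(0, max observed spacing). This literal reading produces
  the very large D values that clustered sets show, but its p-value
  inherits the usual caveat that the null's scale is estimated from the
  data.
* **position-uniform**: one-sample KS of midpoint/chromosome-length
  against U(0,1).
* **montecarlo**: the statistic is the two-sample KS D between the
  observed spacings and spacings pooled from 1000 uniform placements with
  matched per-chromosome gene counts; the p-value is the Monte-Carlo rank
  of that D among the same statistic computed for each simulated
  placement against the pool. A plain two-sample KS p-value is *not* used
  because spacings within one placement are negatively dependent (they
  share a length budget), which makes the asymptotic two-sample
  distribution wildly conservative — measured type-I rate 0.2% at
  nominal 5%. The rank-based p is calibrated by construction; we measure
  4.4% rejection at α = 0.05 over 500 uniform replicates, and 100%
  rejection for placements in 10 clusters with sd = 0.5% of chromosome
  length.

One-sample p-values use the asymptotic Kolmogorov distribution. The
chi-square comparison against a reference gene set bins observed spacings
at reference-spacing quantiles (equal expected mass), with the bin count
max(6, floor(n/30)) — chosen so typical set sizes of ~490 and ~80 genes
give 16 and 6 bins — and df = bins − 1; bins with expected counts below 5
are refused. The reference ("functionally conserved") set is the
equal-sized set of highest-CpG_o/e genes, the least-methylated,
housekeeping-like end of the distribution. Centromere positions are user
input (e.g. read from a Hi-C contact map); chromosomes without one report
"not available" rather than zero proximal genes.

## Duplication screens

Depth quartiles use linear interpolation (type 7); the duplication flag is
depth > Q3 + k·IQR with k = 1.5 by default. Low-side deviations are
flagged separately but not counted as duplication outliers, since only
collapsed repeats inflate depth. The screen is invariant under uniform
rescaling of depths, so reads-per-gene and mean-coverage units are equally
acceptable; a per-base BED aggregator (mean over gene span) is provided.

Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site fractions
under the universal code (changes to stop codons count as nonsynonymous),
sites averaged between the two sequences, multi-hit codons averaged over
all orderings of the differing positions, and the Jukes–Cantor correction
Ks = −¾ln(1 − 4/3·ps) with ps ≥ 3/4 reported as saturated (infinite).
This is a deliberate desk-scale substitute for maximum-likelihood codon
models (F3×4); at the low divergences where recent-duplication claims
live (Ks ≲ 0.1) the two agree closely, which is the regime the recovery
tests exercise. The implementation is cross-checked in the test suite
against an independent NG86 implementation (Biopython's `cal_dn_ds`) and
against exhaustive pathway enumeration on single codons. Ks histograms
exclude saturated pairs (counted separately) and report the fraction of
pairs inside configurable age windows, inclusive at both ends.

## Comparative statistics

Order-level trait comparisons are unpaired, so the pairwise test is the
rank-sum (Mann–Whitney) test — "signed-rank" applies to paired data and is
read here as the rank-sum test. Tie-free pairs with ≤ 25 values per group
use the exact null distribution; otherwise the normal approximation with
tie and continuity correction is used, BH-adjusted across pairs.
Kruskal–Wallis uses midranks with tie correction and a chi-square
p-value, adequate at the group sizes these comparisons involve. The Ne
calculator returns θ_W/(4μ) exactly and as an order of magnitude
(10^round(log₁₀ Ne)), the scale at which such estimates are quoted.
No phylogenetic correction is applied; species are treated as exchangeable
within orders, as the trait values are taken as tabulated.

## k-mer genome size

Canonical k-mers (lexicographic minimum of the k-mer and its reverse
complement; k must be odd) are counted in a plain in-memory hash — the
intended scale is ≤ ~10⁷ k-mers. The error cutoff is the first local
minimum of the 3-point-smoothed histogram, or multiplicity 1 when the
histogram rises from the start (no error k-mers). The reported `peak` is
the modal multiplicity above the cutoff, but the size estimate divides the
instance total by the count-weighted mean multiplicity within
peak ± 3√peak rather than by the integer mode: the mode's granularity
alone moves the estimate by ~1/peak (≈ 4% at 25× k-mer coverage) when
sampling noise flips the mode by one unit, while the windowed mean tracks
the true per-k-mer coverage to a few tenths of a percent, remains exact
on a degenerate single-multiplicity histogram, and still excludes error
k-mers below and repeat k-mers above. The estimator targets homozygous or
inbred samples; no heterozygosity or repeat-structure modeling is
attempted.

## Synthetic data: what it emulates and what it does not

The generators define the conditions every recovery test runs under:

* **Genome**: 4 chromosomes (the copepod karyotype scale) of 2 Mb with
  125 intronless genes of 1500 nt each by default; base composition fixed
  at GC = 33% (AT-rich, matching the genomes these analyses were designed
  around). Placement is uniform, or Gaussian clusters (10 per chromosome,
  sd = 0.5% of chromosome length by default) around uniform centers, with
  gene overlap resolved by resampling and a uniform fallback for
  saturated clusters. Centromeres sit at chromosome midpoints.
* **CDS model**: a first-order Markov chain whose transition matrix is
  constructed so its stationary distribution equals the base composition
  exactly while P(G|C) = w·p_G; consequently the expected CpG_o/e of
  emitted sequence equals the CpG-odds parameter w, making
  generator→estimator closure a sharp test (mean measured CpG_o/e within
  ±0.05 of w at 500 genes × 1500 nt). The default w = 0.5 reproduces a
  strongly depleted genome; ion-transport-labeled genes can be given a
  lower w to emulate deeper historical methylation of that set. The chain
  reproduces dinucleotide statistics, not mutation history: it contains
  no selection, codon structure, or C→T deamination process.
* **Depths**: negative binomial with mean 100 and dispersion (size) 200,
  i.e. variance 1.5× Poisson — modest overdispersion appropriate to
  uniform short-read coverage of an inbred sample. A 5% fraction of genes
  is multiplied by 10 to plant duplicates. These defaults were fixed by a
  design calculation: the exact NB tail beyond the contaminated-cohort
  IQR fence predicts ~4 false flags per 1900 null genes against 100
  planted duplicates, giving the screen comfortable margins (sensitivity
  ≥ 0.9, FDR ≤ 0.1) rather than a knife-edge pass.
* **Paralogs**: random sense-codon ancestors; each copy receives
  Poisson(Ks/2 · S) strictly synonymous single-nucleotide changes drawn
  uniformly from the current sequence's synonymous-change set, so the
  pair's expected NG86 divergence is the target Ks. Mixtures of targets
  generate bimodal Ks plots. No nonsynonymous change, rate variation, or
  codon-usage bias is simulated.
* **Reads**: fixed-length reads (125 bp default) from uniform start
  positions on both strands; error-free by default, with optional uniform
  substitution errors. Read length 125 at 30× gives per-k-mer coverage
  λ = 30·105/125 = 25.2 for k = 21 — deliberately non-integer so the
  histogram has an unambiguous mode.
* **Trait tables**: lognormal values around per-group medians with a
  configurable coefficient of variation.

Because these generators capture the *statistical* structure the analyses
assume and nothing else, passing tests demonstrate that the estimators
recover their own generative parameters and that the test procedures are
calibrated and powered under those conditions — not that real genomes
satisfy the generators' assumptions (no repeats, no introns, no
sequencing bias, independent genes).

## Problem sizes

The shipped studies use the scales above: KS calibration over 500
replicates of 80-gene placements with a 1000-placement Monte-Carlo null
per replicate; power over 200 clustered replicates; CpG closure at 500
genes × 1500 nt per target; Ks recovery on 200 pairs × 300 codons; the
depth screen on 2000 genes; k-mer sizing on a 100-kb region at 30×.
These sizes give each check sampling error several times smaller than its
tolerance while keeping the whole suite fast.

## Known limitations

* The literal uniform-spacing KS null treats the estimated maximum
  spacing as the null scale, which biases D slightly; it is retained
  because its large D values are the field's familiar summary, while the
  Monte-Carlo mode is the defensible inference path.
* NG86+JC underestimates Ks at high divergence relative to ML codon
  models; saturated pairs are reported, not corrected.
* The enrichment engine is flat: related terms are not merged and no
  parent-term propagation occurs.
* The k-mer estimator has no error/heterozygosity mixture model; reads
  with realistic error profiles need the cutoff heuristic verified on
  their histogram.
* Chromosome-number/genome-size comparisons are non-phylogenetic.
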