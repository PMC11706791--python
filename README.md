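# copegen

Genome-architecture analyses for small, compact crustacean genomes,
modeled on the questions raised by the chromosome-scale genome of the
euryhaline copepod *Eurytemora carolleeae*: does the genome carry the
sequence signature of pervasive historical gene-body methylation, are
ion-transport genes physically clustered on chromosomes, how much recent
gene duplication is there, how do karyotype and genome size compare across
copepod orders, and what genome size do the raw reads imply?

The package is organised as an analysis project: every computation lives in
the library under `src/copegen/`, the numbered scripts under `analysis/`
drive the full study on synthetic data with known truth, and `tests/`
checks each statistic against independent oracles.

## The statistics at the core

* **CpG observed/expected ratio.** For a coding sequence of length L,
  CpG_o/e = f_CpG / (f_C · f_G) with f_C = n_C/L, f_G = n_G/L and
  f_CpG = n_CpG/(L−1) over overlapping dinucleotide windows. Methylated
  cytosines deaminate to thymine over evolutionary time, so genes with a
  history of gene-body methylation show CpG_o/e well below 1; a unimodal
  distribution with a low mean is the signature of genome-wide historical
  methylation.
* **Spatial clustering.** For a labeled gene set, adjacent-gene spacings
  (differences of consecutive gene-span midpoints, pooled over
  chromosomes) are tested against a uniform null with the
  Kolmogorov–Smirnov statistic D = sup|F̂(x) − F₀(x)| under three null
  conventions (literal Uniform(0, max spacing), uniform positions, and a
  Monte-Carlo null of matched uniform placements), and against a
  housekeeping-like reference set (the genes with the *highest* CpG_o/e)
  with a chi-square goodness-of-fit on equal-mass bins.
* **Duplication screens.** Genes with depth > Q3 + 1.5·IQR of the per-gene
  read-depth cohort are flagged as putative duplicates, and paralog pairs
  are dated by synonymous divergence Ks estimated with Nei–Gojobori (1986)
  counting plus the Jukes–Cantor correction
  Ks = −¾ ln(1 − 4/3·ps).
* **Comparative statistics.** Tie-corrected Kruskal–Wallis H and pairwise
  rank-sum tests across taxonomic orders, group medians, Pearson r, and
  the neutral-theory calculator Ne = θ_W / (4μ).
* **k-mer genome size.** Canonical k-mer multiplicity histograms peak at
  the per-k-mer coverage λ = c(r−k+1)/r; genome size is the number of
  k-mer instances above the error cutoff divided by the measured peak
  coverage.

A first-class synthetic-data module generates genomes (Markov-chain coding
sequences with a tunable CpG-odds parameter equal to the expected CpG_o/e,
uniform or clustered gene placement), negative-binomial depth tables with
planted duplicates, paralog pairs at known Ks, reads, and order-labeled
trait tables — each with a truth JSON, so every analysis is scored against
known ground truth.

## Worked example

```bash
cd analysis
python 01_simulate.py && python 02_cpg_landscape.py && python 04_spatial_clustering.py
```

prints (abridged):

```
synthetic genome: 500 genes on 4 chromosomes of 2,000,000 bp (clustered placement, ...)
500 genes: mean CpG_o/e = 0.477 (sd 0.111), 100.0% below 1 (1 density mode(s))
ion-transport subset mean CpG_o/e = 0.364 (80 genes)
KS [uniform-spacing  ]: D = 0.641, p = 1.46e-27
KS [position-uniform ]: D = 0.259, p = 4.44e-05
KS [montecarlo       ]: D = 0.417, p = 0.000999
```

The genome was generated with CpG-odds 0.5 genome-wide and 0.35 for the
80 ion-transport genes, so the measured means (0.477 and 0.364) recover the
generative targets; the clustered placement is detected by all three KS
nulls, with the Monte-Carlo mode giving the calibrated p-value. The
remaining scripts run the enrichment engine on the low-CpG tail
(`03`), both duplication screens (`05`, recovering the planted 5%
duplicated genes with sensitivity 1.00 and the 60/40 young/old paralog
mixture), the order-level comparisons and Ne calculator (`06`), and the
k-mer size estimate (`07`, within 0.3% of the true 100-kb region).

Each stage is also exposed as a CLI (`copegen simulate|cpg|enrich|cluster|
depth-outliers|ks-plot|compare|kmersize|run`) and as a single configurable
pipeline (`copegen run --config cfg.json`) that emits a schema-validated
JSON report.

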