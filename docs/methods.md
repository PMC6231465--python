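# Methods

`milupop` implements the population-genomic analyses used to characterise a
long-bottlenecked, recovering population — the motivating system is the Milu
(Père David's deer), a species rebuilt from a small captive herd — from a
variant call set and a handful of comparative-genomics tables. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data validation does and does not demonstrate.

## Runs of homozygosity and Froh

ROH detection follows the sliding-window logic of PLINK 1.07 `--homozyg`
with the flag set appropriate to low-coverage (~11–14×) resequencing:
65-SNP windows qualifying with at most 1 heterozygous and 3 missing calls, a
SNP eligible when ≥ 5% of its containing windows qualify, candidate runs of
consecutive eligible SNPs split at > 5,000 kb gaps, and segments kept with
≥ 65 SNPs, ≥ 100 kb span and ≤ 5,000 kb/SNP; the bp-window constraint is
disabled (`window_kb = 0`). Three behaviours PLINK leaves implicit are fixed
here: windows truncated at scaffold ends are not formed (the hit-rate
denominator is the actual number of containing windows); segment boundaries
are the first/last member SNP positions; heterozygous or missing calls
interior to a run remain members (missing calls are "transparent" — they
neither qualify a SNP nor break a run). These choices are validated not
against PLINK but against a brute-force oracle that materialises every
window explicitly.

Froh is total ROH length over the genome's effective length. "Effective
length" has no universal formula; the default here is the summed length of
scaffolds carrying at least one called SNP for the sample, overridable where
a cohort has an agreed assayed-genome figure.

## SNP-density segmentation

Per-window SNP density (SNPs/kb; 200-kb windows, 2-kb steps, scaffolds
> 300 kb) is modelled as a two-regime process. A two-component Gaussian
mixture is fitted by EM — one quantile-split initialisation plus four random
restarts, variance floored at sd ≥ 1e-4 SNPs/kb to prevent component
collapse, best log-likelihood kept, components sorted by mean. The mixture
initialises a two-state Gaussian HMM (state 0 = lower mean = "L"),
transitions initialised self-biased at 0.99 because multi-megabase blocks
are the object of inference; Baum–Welch treats scaffolds as independent
sequences sharing one genome-wide parameter set; Viterbi decodes the state
path with ties broken toward L for deterministic output. Densities are
per-kb rates rather than per-window counts; the choice only rescales the
emission scale.

Window states map back to base pairs by step-interval ownership: the 2-kb
interval at each window's start takes that window's state, and the final
window of a scaffold extends to its window end. Because a window's density
summarises the 200 kb *ahead* of its start, decoded block boundaries shift
by up to ~90 kb around true regime changes; this is immaterial when blocks
are an order of magnitude longer than the window (the regime the method is
meant for) and is why the genome simulator defaults to 5-Mb blocks (below).

## Heterozygosity, relatedness, deleterious fractions

Heterozygosity is heterozygous-SNP density per kb, genome-wide (denominator:
summed scaffold length) and per element class after partitioning scaffolds
into exon / intron (gene span minus exons) / other (complement of genes).
The partition is exact, so per-class counts recombine to the genome-wide
count — a conservation law the tests assert.

Relatedness is the unadjusted Yang-type moment estimator (what the VCFtools
relatedness screen reports): a_jk averages
(x_j − 2p)(x_k − 2p) / (2p(1−p)) over sites called in both samples. Degree
bands on a_jk are KING-style: > 0.354 duplicate, (0.177, 0.354] 1st,
(0.0884, 0.177] 2nd, (0.0442, 0.0884] 3rd, else unrelated; the "unrelated"
cutoff is configurable because published cohort tables sometimes label
values in the 3rd-degree band as unrelated. Allele frequencies default to
in-sample estimates, which are strongly biased for tiny cohorts (n = 5
pushes unrelated pairs toward ≈ −1/(n−1); a duplicated pair judged on its
own two columns is identically 0), so a known frequency vector can be
supplied; quantitative recovery tests use the generator's true frequencies,
while classification behaviour is additionally exercised with in-sample
estimates.

Deleterious summaries report per-sample percent deleterious among annotated
missense variants. The denominator is a mode flag — DE/(DE+TO) by default,
DE/(DE+TO+OT) available — since published percentages rarely state which
was used; the cohort mean is unweighted over samples.

## Lineage evolution

Rapidly evolving GO categories: families carry per-lineage nonsynonymous
counts A (and rates Ka); for each category with ≥ 15 mapped families
(set semantics over the family→GO map; no ontology propagation, since
mappings inherited from a reference annotation are used as given), a
one-sided Wilcoxon signed-rank test asks whether the foreground lineage
exceeds the background, paired by family; unpaired (rank-sum) comparison is
exposed as a mode. Zero differences are dropped and reported; |differences|
are mid-ranked. For ≤ 25 effective pairs the p-value is the exact
conditional sign-flip null (subset-sum DP on doubled mid-ranks, so ties are
handled exactly); beyond that, the normal approximation with tie-corrected
variance and a 0.5 continuity correction. The two regimes agree to within a
few percent relative p except in the extreme tail, where any normal
approximation degrades. Significance is declared at p < 0.025, and the
analysis is run for A and repeated for Ka.

Positively selected genes: 2(lnL_alt − lnL_null) from branch-site model
fits, clamped at zero (negative deltas beyond 1e-6 are logged), referred to
the χ²₁ upper tail — conservative relative to the 50:50 boundary mixture —
then multiplicity-corrected. Bonferroni is the default (matching a
"corrected p < 0.01" selection rule); Benjamini–Hochberg is available
because "false discovery rate with Bonferroni correction" descriptions in
the literature are ambiguous.

## Synthetic data: what it emulates, what it does not

The generators provide every stage's input with serialised truth, seeded by
component (`default_rng([seed, component_id])`) so outputs are
byte-identical under a fixed seed and adding a component never perturbs the
others.

- **Two-regime genome**: alternating exponential blocks (default mean 5 Mb
  per state, i.e. low state stationary fraction 0.5) set a local SNP rate of
  0.03 or 1.26 SNPs/kb; SNP positions are Poisson, allele frequencies
  Beta(0.8, 0.8) (a U-shaped folded spectrum), genotypes HWE. Gene models
  (20 per scaffold, 5–20 kb, 3–8 exons) are placed uniformly.
- **Inbred samples**: IBD tracts as an alternating renewal process with
  exponential lengths (mean 2 Mb) at target coverage F on a uniform ~2-kb
  SNP lattice; genotypes forced homozygous inside tracts with heterozygous
  flips at the genotyping error rate (default 0.005, a plausible figure at
  ~10–15× coverage), HWE outside.
- **Related pairs**: one haplotype copied identically-by-descent on exactly
  round(c·200) of 200 site blocks, with c = 1.0 / 0.5 / 0.25 / 0 for
  duplicate / 1st / 2nd degree / unrelated, giving E[a_jk] = c/2.
- **Family tables**: per-family A ~ Poisson(6) in both lineages; planted
  categories draw the foreground at twice the rate; Ka divides by a shared
  per-family nonsynonymous site count (500–1,500).
- **LRT nulls**: a one-parameter boundary-constrained Gaussian MLE
  (μ ≥ 0 vs μ = 0), whose statistic is the ½δ₀ + ½χ²₁ boundary mixture —
  the same situation that makes the χ²₁ reference conservative.

One deliberate calibration: the block and tract layouts are
rejection-resampled until realized coverage is within 0.02 (states) / 0.01
(tracts) of the nominal stationary fraction / F. A 100-Mb genome holds only
a handful of multi-megabase blocks, so an unconditioned layout's coverage
varies by ±0.05–0.07 between seeds; conditioning makes recovery tests
measure estimator error against the planted level rather than layout noise.

What passing these tests shows: the window scan, segmentation, Froh,
relatedness and test procedures are algorithmically correct and well
calibrated under their own model assumptions. What they do not show:
robustness to real-data pathologies — reference mis-assembly (which breaks
long ROH), mapping artefacts, allele-frequency ascertainment, LD,
recombination-rate variation, or non-Gaussian density regimes. No
coalescent or read-level realism is attempted.

## Problem sizes and tolerances

The validation suite runs the stages at the scales the analyses are designed
around: 100-Mb genomes (ten 10-Mb scaffolds), ~50,000 density windows,
~50,000-SNP cohorts, 50,000-site pairs, up to 10,000 category tests and
10,000 LRT replicates; the brute-force ROH oracle is applied to instances of
up to 2,000 SNPs. Convergence tolerances are 1e-8 (mixture EM, log-likelihood
delta) and 1e-6 (Baum–Welch); EM iteration caps 1000/500. Degenerate inputs
fail loudly: identical densities (no mixture), all-zero differences (p = 1
with a flag), monomorphic-only relatedness input, overlapping ROH segments
in Froh.
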