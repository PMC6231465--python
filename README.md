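# milupop

Inbreeding and diversity genomics for recovered bottleneck populations.

Conservation programs that rebuild a species from a few founders — the
motivating case is the Milu (Père David's deer), re-established from a small
captive herd — need to quantify, from whole-genome variant calls, how much
inbreeding the population carries, how its remaining diversity is
distributed along the genome and across genomic elements, whether the
sequenced individuals are secretly relatives, and which genes or functional
categories evolved unusually fast on the lineage. `milupop` implements that
analysis stack as a tested Python library with a CLI, plus synthetic-genome
generators that provide ground truth for every stage.

## What it computes

- **Runs of homozygosity and Froh** — a PLINK 1.07-style sliding-window scan
  (65-SNP windows, ≤ 1 het / ≤ 3 missing, hit-rate threshold 0.05, segments
  ≥ 65 SNPs and ≥ 100 kb, 5,000-kb gap/density limits) and the inbreeding
  coefficient F<sub>ROH</sub> = Σ ROH length / genome effective length.
- **SNP-density segmentation** — per-window SNP densities (200-kb windows,
  2-kb steps, scaffolds > 300 kb), a two-component Gaussian mixture fitted
  by EM, a two-state Gaussian HMM fitted by Baum–Welch, and Viterbi decoding
  into low/high-density (L/H) genomic blocks with genome- and SNP-fraction
  summaries.
- **Heterozygosity** — het SNPs per kb genome-wide and per element class
  (exon / intron / other), with ratios to the genome-wide rate.
- **Relatedness** — the Yang-type moment estimator
  a_jk = mean_i (x_ij − 2p_i)(x_ik − 2p_i) / (2p_i(1 − p_i)) with KING-style
  degree bands (duplicate / 1st / 2nd / 3rd degree / unrelated).
- **Deleterious-variant summaries** — per-sample percent deleterious among
  annotated missense variants, with an explicit denominator mode.
- **Rapidly evolving GO categories** — per-category one-sided Wilcoxon
  signed-rank tests (exact conditional null up to 25 pairs, tie-corrected
  normal approximation beyond) on paired per-family A or Ka values,
  categories with < 15 orthologues excluded, significance at p < 0.025.
- **Positively selected genes** — branch-site LRT 2ΔlnL against χ²₁ with
  Bonferroni (default) or Benjamini–Hochberg correction, selection at
  corrected p < 0.01.
- **Synthetic data** — two-regime genomes, inbred samples with planted IBD
  tracts at target F, sample pairs at chosen kinship, and family tables with
  planted accelerated categories; byte-deterministic under a seed, truth
  serialised to JSON.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
inputs with known truth:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_density_segmentation.py
python analysis/03_roh_froh.py
python analysis/04_diversity_relatedness.py
python analysis/05_lineage_selection.py
```

`02` segments a 100-Mb genome whose low-density state truly covers half the
sequence at 0.03 SNPs/kb against 1.26 SNPs/kb:

```
mixture: means [0.031 1.234] SNPs/kb, weights [0.501 0.499]
low-density state covers 50.1% of the segmented genome and holds 2.6% of SNPs
mean het: L 0.024/kb, H 0.916/kb
window-state agreement with truth: 98.8%
```

— i.e. half the genome carries under 5% of the SNPs, the hallmark of
descent-driven homozygosity rather than uniformly low diversity. `03` calls
ROH on a five-sample cohort simulated at mixed inbreeding levels:

```
 sample  true F    Froh  n_seg  mean kb   >1Mb
   lib2   0.160  0.1686      9     1874   0.97
   lib3   0.130  0.1286     10     1286   0.73
   lib4   0.110  0.1005      8     1256   0.62
   lib5   0.140  0.1469     10     1469   0.86
   lib6   0.120  0.1126      8     1408   0.89
Froh ranking matches simulated F ranking: True
```

Froh recovers each sample's simulated F to about ±0.01 and preserves the
ranking, with most ROH length in segments longer than 1 Mb — the signature
of recent inbreeding. `05` recovers all ten GO categories planted at a
two-fold nonsynonymous acceleration (for both A and Ka) with false positives
at the nominal rate.

The same stages are available as subcommands of the `milupop` CLI
(`simulate`, `density-segment`, `roh`, `froh`, `het`, `relatedness`,
`rapid-go`, `psg-lrt`, `run-all`, `report`); `run-all` takes a YAML config
and writes a manifest with per-stage checksums for reproducibility.

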