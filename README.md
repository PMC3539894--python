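# noiseplast

Analyses of how gene-expression **noise** (cell-to-cell stochasticity) and
**plasticity** (responsiveness across environmental conditions) couple and
uncouple across the *Saccharomyces cerevisiae* genome, for researchers in
regulatory genomics and epigenomics.

Two regulatory regimes separate the two kinds of variability:

* In **highly plastic (HP)** genes, coupling is transcriptional. A gene's
  *chromatin regulation effect* (CRE) is the mean of |z<sub>gm</sub>| over
  chromatin-regulator deletion profiles m, where z<sub>gm</sub> is the
  log₂ expression ratio of gene g in mutant m after scaling each profile
  to unit variance. High CRE brings plasticity everywhere, but noise only
  where promoters combine high proximal nucleosome occupancy (mean log₂
  occupancy in −100..0 bp from the TSS) with a TATA box. Low-noise HP
  genes (LNHP) are driven by general activators; noisy HP genes (HNHP) by
  gene-specific repressors — and most histone mutants act dually,
  de-activating LNHP while de-repressing HNHP genes.
* In **low-plasticity (LP)** genes, noise is translational: it rises with
  translational efficiency and ribosome density, which in turn fall with
  ORF length.
* **Genome organization** modulates only the transcriptional regime:
  bidirectional promoters (a shared nucleosome-depleted region driving two
  divergent transcripts) abate noise in HP genes, and intergenic distance
  rank-correlates with plasticity.

The package provides the full pipeline: typed readers/writers for gene
tables, mutant compendia (TSV), transcript maps (BED6+3) and occupancy
tracks (bedGraph); quartile-based variability classification; CRE/HRE
scoring; strand-aware promoter-window summarization; the binned
permutation test and sliding-window randomization with mean ± 2 SD
envelopes; neighborhood architecture classification (bipromoter /
divergent / parallel × coding / noncoding partner); and a synthetic-data
generator that plants all of these effects with known truth, so every
stage is testable end to end without external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic genome (2000 genes, 170 mutant profiles, 16 chromosomes) and
write their tables under `results/`:

```
cd analysis
python 01_simulate.py --seed 1
python 03_chromatin_regulators.py --seed 1
```

prints

```
CRE vs plasticity: Spearman rho=0.539 (p=4.23e-151, n=2000)
regulator specificity scatter: rho=-0.851 (p=5.99e-49) — strong anti-correlation = complementary HNHP/LNHP programs
histone mutants decreasing LNHP while increasing HNHP: 82%
```

i.e. the pipeline recovers the planted CRE–plasticity coupling (target
ρ = 0.57; the CRE score estimates it at 0.539 from the compendium), the
anti-specific regulator program (mutants that hit HNHP hard spare LNHP
and vice versa), and the dual action planted in 81% of histone mutants.
`05_translation_sliding_window.py` shows translational efficiency rising
(4.00 → 5.01) and ORF length falling along the noise ordering of LP
genes; `06_neighborhood.py` reports the bipromoter noise reduction in HP
genes (mean noise 0.060 vs 0.079, Wilcoxon p = 6.5 × 10⁻⁵) and the
bipromoter enrichment of LNHP over HNHP genes (OR = 3.1, Fisher
p = 7.9 × 10⁻⁴); `07_contingency_tables.py` recomputes the published
2×2 statistics exactly (e.g. TATA depletion in LP genes, Yates χ²
p = 1.7 × 10⁻¹⁸).

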