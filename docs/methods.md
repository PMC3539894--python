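# Methods

## Variability measures and classes

Noise enters as a distance-to-median (DM) score — cell-to-cell protein
variability with the abundance trend removed — plasticity as the sum of
squared log₂ expression ratios over many growth conditions, and
divergence as between-species expression variation. All three are
min–max scaled to [0, 1] on the full table before any subsetting, so
subgroup means remain comparable. Noise and plasticity are each cut at
their 25th/75th percentiles (linear interpolation between closest
ranks; configurable via `percentile_method`) into low/medium/high.
Values exactly at a boundary are *medium*: strict inequalities keep the
tail classes pure, and classification is then invariant under any
strictly increasing transform of the measure. Joint classes LNLP, LNHP,
HNLP, HNHP take only the tail combinations; any medium component maps
to `other`. LP/HP denote the full low-/high-plasticity margins
(including medium noise). Noise-sensitive genes are essential genes or
protein-complex subunits, minus haploinsufficient genes (for which low
expression, hence low noise, is not an option).

Noise and plasticity are classified per measure on all non-missing
values rather than on the intersection set; the per-analysis n
therefore varies with missingness, which the TSV readers preserve
(empty cell → NA, never 0).

## Chromatin regulation effect

Each mutant profile (log₂ ratios, deletion vs wild type) is divided by
its sample (n−1) standard deviation over non-missing entries. The mean
is *not* subtracted (configurable with `center_columns`): log₂ ratios
are already centered on no-change = 0, and subtracting a column mean
would shift the zero point that the sign analyses depend on. CRE is the
per-gene mean of |normalized value| over the chromatin-tagged mutants;
HRE over the histone-tagged ones. Whether the "general" (TAF1-like)
profiles should enter CRE is genuinely ambiguous in the source
description; the default is chromatin-only, switchable with
`cre_classes`. Genes observed in fewer than half the selected mutants
(`min_fraction_observed`) get a missing score. CRE is invariant to
rescaling any compendium column; it is zero only if every observed
entry is zero, which unit-variance normalization makes practically
impossible.

Regulator-level quantities normalize each mutant's mean |effect| on
HNHP and on LNHP by its mean |effect| on the **full HP margin**. The
full margin matters: normalizing by HNHP∪LNHP alone forces the two
ratios to average to ~1 jointly and drives their correlation to −1 by
construction. Even with the full margin the shared denominator induces
a structural baseline anti-correlation of about −0.3 between the two
ratios under a null compendium (the zero-effect generator measures it
at −0.30 to −0.41); the planted anti-specific program pushes it to
about −0.85. "Decreased expression" means strictly negative normalized
value; zeros count as unchanged. The dominant sign of a regulator is
*activating* when deletion decreases expression in strictly more than
half of the observed genes; an exact 50/50 split is reported repressing
and flagged ambiguous.

## Promoter occupancy windows

Proximal occupancy is the mean log₂ occupancy in −100..0 bp from the
TSS (101 positions, TSS included — the 1 bp ambiguity of "0" is fixed
this way and immaterial to window means), distal in −400..−150 bp (251
positions). Windows mirror genomically on the minus strand and are
clipped at chromosome position 1; a window with no overlapping track
points is missing, never zero. Interval-valued track points are
assigned to windows by midpoint; `window_assignment=overlap_weighted`
switches to overlap-length weighting for sensitivity analysis.

## Randomization procedures

**Binned permutation test.** Genes with complete (occupancy, CRE,
outcome) triples are sorted by occupancy and cut into `n_bins` = 10
contiguous bins whose sizes differ by at most one (larger bins first;
ties broken by stable input order). Within each bin, genes strictly
above the bin-median CRE form the "above" group; at-median genes go
below, which guarantees both sides are non-empty even when most of a
bin shares the median. The statistic is mean(outcome|above) −
mean(outcome|below); the null permutes the outcome within the bin
(equivalent under the null to shuffling the split labels) `n_perm` =
10000 times, and a bin is significant outside null mean ± 2 null SD.
An optional switch replaces the ±2 SD rule with empirical quantiles.

The ±2 SD rule's nominal two-sided rate is 4.55% only insofar as the
permutation null of the bin delta is normal. Calibration runs use bins
of 60 genes: at 30 genes/bin the delta's tails are measurably light
(null flag rate 3.99%), while at 60 the nominal rate holds (4.60%
over 10⁶ bin-tests at n_perm = 1000); the real analysis has ~200
genes/bin, so larger calibration bins are also the representative
choice. Calibration uses 1000 replicates at n_perm = 1000 — a
scaled-down permutation count; the analysis drivers use the full
10000.

**Sliding window.** Genes are sorted by the ordering variable (stable
on ties) and the response is averaged in windows of `window_size` = 100
genes, step 1. The window size is a free choice; conclusions in the
drivers are insensitive to it by construction (monotone trends).
Observed window means are computed per-window with `np.mean` over a
contiguous view so they are bit-identical to a naive loop; the null
envelope (global shuffles of the response, per-position mean and
sample SD) uses a cumulative-sum profile for speed, which is
statistically — not bit — equivalent and never compared elementwise to
the observed profile.

All randomized procedures consume a single seeded generator stream in
documented order and are bit-reproducible given (seed, n_perm).

**Standard tests.** Spearman with average ranks and t-approximation
p-values, two-sided; Fisher's exact test two-sided by the
minimum-likelihood method, with the unconditional odds ratio ad/bc;
the 2×2 chi-square applies the Yates continuity correction (the
uncorrected statistic does not reproduce the published TATA-depletion
p-value, the corrected one does); rank-sum via Mann–Whitney with
average-rank ties; Benjamini–Hochberg for FDR. These delegate to
scipy/statsmodels behind one audited surface; the test suite checks
them against exhaustive-enumeration oracles on small instances.

## Neighborhood architecture

The upstream partner of a focal transcript is the nearest transcript
whose focal-facing edge lies before the focal TSS in the focal gene's
reading direction (ties broken lexicographically by transcript id).
All transcript kinds — coding ORF-Ts and noncoding CUTs/SUTs — are
candidates. An opposite-strand upstream partner necessarily points
away, so orientation is *divergent* iff strands differ. Intergenic
distance runs from the focal TSS to the partner's facing edge, which
is the partner TSS for divergent and the partner TES for parallel
pairs; this is the geometrically unambiguous reading of "distance to
the upstream partner", and `distance_mode=span_gap` provides the
span-gap alternative. Genes whose partner is a dubious ORF or
pseudogene, whose nearest upstream transcript overlaps their span, or
that have no upstream transcript are excluded from architecture
summaries with a recorded reason. Bipromoter status is an input
annotation from shared-NDR calls, not inferred; it is only consistent
with divergent orientation and the pipeline errors on violations.
Every construction is invariant under reversing a chromosome's
coordinates and flipping all strands.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs,
not their biology: no real sequences, gene names, or exact marginals.
Rank-correlation targets are planted by Gaussian copula — latent
normals correlated at r = 2 sin(πρ/6), then transformed to the working
marginals — so each Spearman target is exact in expectation regardless
of marginal shape. Defaults are the magnitudes the pipeline is built
to detect: CRE–plasticity ρ = 0.57, LP noise–TE ρ = 0.22,
distance–plasticity ρ = 0.19, TATA frequency 5% in LP and 35% in HP,
median intergenic distance 204 bp, 170 mutants split
120 chromatin / 10 general / 40 histone.

Gene table: plasticity is log-normal (right-skewed); TE declines with
log ORF length (planted at ρ ≈ −0.58) with a codon-bias contribution;
ORF lengths are log-normal, 12% longer for essential genes; LP noise
follows the TE copula, HP noise follows proximal occupancy plus a
TATA × occupancy × CRE interaction, medium-plasticity noise is free.
Compendium entries are A_g·(shift + ε) with A_g the gene's CRE latent:
chromatin mutants split into LNHP-specific activators (negative
shift on LNHP), HNHP-specific repressors and unspecific mutants, with
non-target responses scaled down exactly enough that a planted gene's
expected mean |response| over the chromatin class equals the
unplanted baseline — the class structure therefore does not distort
the planted CRE–plasticity coupling. General mutants decrease
expression genome-wide, more strongly in LNHP; ⌈81%⌉ of histone
mutants act dually (decrease LNHP, increase HNHP), the rest decrease
both. Genome: transcripts are laid sequentially on 16 chromosomes with
gaps sampled from the plasticity copula via an ownership rule (a gap
belongs to the downstream gene when it reads away from it, to the
upstream gene when that one reads toward it, averaged when both claim
it — the divergent case); divergent-facing pairs are flagged
bipromoter with probability decaying in the gap; noise of HP
bipromoter genes is then reduced by 0.5 noise-SD, which is what makes
LNHP bipromoter-enriched downstream. CUTs/SUTs interleave at rate
0.15, and 5% of genes receive an explicit decoy partner
(dubious/pseudogene/overlapping) so filter counts are known. The
occupancy track is built at 10 bp resolution with promoter windows set
to each gene's planted level.

What passing recovery tests shows — and does not. They show the
pipeline measures what was planted at the planted strength under
clean, near-Gaussian dependence with missingness at random. Real data
differ: heavier-tailed marginals, confounded covariates (expression
level, growth rate), structured missingness, and probe-level
occupancy artifacts. Recovered correlations are also mildly attenuated
relative to the planted latents (CRE scoring noise ≈0.02–0.03 of
Spearman; gap sharing and noncoding partners attenuate the
distance–plasticity target from 0.19 to ≈0.15), which the recovery
tolerances absorb.

## Problem sizes and determinism

The default study is 2000 genes — enough that quartile subclasses hold
~100–140 genes, matching the published subclass sizes (66–236). Test
and acceptance runs use 10000 permutations only where they are cheap;
calibration runs at n_perm = 1000 × 1000 replicates. Everything
downstream of a `SyntheticConfig` is byte-deterministic given its
seed; the three generator stages use seed, seed+1, seed+2 so each is
independently callable.

## Known limitations

* The real upstream datasets are not redistributed; analyses of real
  measurements enter only through the published 2×2 count tables.
* The extreme proximal-occupancy values of the source arrays are not
  reproduced; the generator's occupancy scale is arbitrary but ordered.
* Fisher's odds ratio is the unconditional ad/bc, not the conditional
  MLE; p-values are unaffected.
* The bipromoter annotation is taken as given; no NDR detection or
  nucleosome calling is performed, and no GO/functional enrichment is
  included.
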