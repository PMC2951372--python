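# Methods

## Scope and model

`tilemark` reimplements, as a library, the analysis stack used to map a
repressive histone mark (H3K27me3) on tiling microarrays in the Arabidopsis
endosperm and to relate the resulting target set to DNA methylation and
expression.  All in-memory intervals are 0-based half-open; GFF3 on disk is
1-based inclusive, BED/bedGraph native half-open.  A single percentile
convention (linear interpolation on order statistics,
`h = (n−1)q`) is used everywhere a quantile appears — gene scores, region
medians, box-plot quartiles, methylation medians — so conventions cannot
drift between modules.

## Probe scoring

The model-based tiling-array (MAT) idea is that probe intensities carry a
strong probe-specific baseline; MAT fits it from 25-mer sequence
composition.  Here the baseline is carried by a scalar **affinity
covariate** per probe (uniform on [0, 1]); the simulator injects it
linearly into log2 intensities and the scorer removes it by standardizing
within `n_affinity_bins = 20` quantile bins of the covariate.  This
preserves the statistical role of the probe model without sequence
machinery.  Standardization is robust by default
(`t = (x − median)/max(1.4826·MAD, floor)`), with a classical mean/SD
option (`robust=False`) for strict MAT emulation; on clean synthetic bins
the two differ negligibly, while median/MAD is stable for small bins.

Enrichment per probe is the replicate-mean of `t_IP − t_control` computed
against both controls (chromatin input and unspecific IgG) and averaged
with equal weight; replicate contrasts are averaged before windowing (the
alternative, scoring replicates jointly, is not exposed because the
averaged contrast is what the window statistic consumes).

The window score is a trimmed mean times √m: all probes whose **start**
lies within ± window/2 (window 500 bp) of the focal probe's start on the
same chromosome are collected, `floor(0.10·n)` values are trimmed from each
end of the sorted window, and the score is `mean(retained)·√m`.  Window
membership by probe start is deterministic and differs from
midpoint-based membership by at most one probe length (25 bp).  Trim
fraction and √m scaling follow the MAT default; only the window size is a
quantity the original analysis states.

With three replicates and two controls the null enrichment has variance
`(1 + 1/4 + 1/4)/3 = 0.5`, so null window scores have SD ≈ 0.71
(independent of m); the 3.5 threshold sits ≈ 5 SD out, and the null
simulation calls no regions in 100/100 seeds.

## Region calling

Qualifying probes (score ≥ 3.5) are chained while the gap between
consecutive qualifying probes — next start minus previous end — is
≤ maxGap = 200 bp; a chain spanning ≥ minRun = 300 bp of genomic span (bp,
not probe count) becomes a region from the first probe start to the last
probe end.  The region score is the maximum probe score (mean and 75th
percentile are available).  Heterochromatin membership is decided by the
region midpoint, which is unambiguous for regions straddling a boundary.

**Boundary resolution.** The positional uncertainty of a called boundary is
set by the score slope at the domain edge: with amplitude A ≈ 2·√m·√2 in
null-SD units and window w, the SD of the threshold crossing is
≈ w/A ≈ 50 bp under the default conditions.  Domain-recovery benchmarks
therefore use base-level recall/precision with 100 bp of boundary slack
(truth eroded by the tolerance for recall, dilated for precision); strict
per-domain matching of both boundaries within 100 bp saturates near
0.7–0.9 for information-theoretic reasons, not implementation ones.
`domain_recovery` reports both the base-level metrics and domain-count
matching.

## Target assignment

Target status is region overlap (≥ 1 bp with the transcribed extent,
half-open semantics), not a gene-score cut-off: overlap reproduces
"genes associated with" the mark, while the 75th-percentile gene score is
reported alongside for box-plot analyses.  Shared/specific classification
is id-level membership in the union of the reference target lists;
per-list classification is available for diagnostics.  The background for
all composition and enrichment statistics is the set of **probed**
features (≥ 1 fully contained probe), never the whole annotation.

## Profiles

Metagene profiles use 20 equal body bins (5% steps) and 2-kb flanks in
100-bp bins, strand-aware; a probe contributes to the bin containing its
start, and the per-bin value is the pooled probe mean across genes
(per-gene-then-average is available via `per_gene_average`).  Chromosomal
densities count elements in the 200-kb window containing their midpoint,
so window totals equal element counts exactly.  Score box plots split
classes at log2 expression 4.2 when expression is supplied (exposed as
`expression_split_log2`).

## Set statistics

Hypergeometric tails are exact (scipy) with both tails computed — the
upper for enrichment, the lower for depletion ("underrepresented").  BH
correction is applied within each family of tests (superfamilies;
categories) separately; category reports flag adjusted p ≤ 1.0E-03.

## Methylation

Element levels are coverage-weighted (`Σ methylated / Σ total`), the
standard estimator for bisulfite-derived counts; zero-coverage elements
are missing, never zero.  Medians are tabulated per feature type for
classes all/specific/shared by context and tissue; CHH is computed but
excluded from default tables because it is uniformly low, with
`include_chh=True` to add it.  Expression clustering is k-means on
row-standardized profiles (Euclidean on standardized rows is equivalent to
correlation distance), fixed seed, 10 restarts; k = 2 for the
repressed/expressed split, k = 5 for the finer tissue clusters.

## Differential expression

The rank product of a gene is the geometric mean of its fold-change ranks
over **one-to-one replicate pairings** (k = min(n₁, n₂) comparisons).
One-to-one pairing, rather than all n₁×n₂ pairs, keeps comparisons
independent, which is what makes the label-permutation null valid: with
all pairs the observed rank products are correlated across comparisons and
permutation p-values are anti-conservative (measured null p < 0.05
fraction ≈ 0.14 versus ≈ 0.05 with pairing).  Up- and down-regulation are
separate one-sided statistics.  The null pool is 1000 permutations of
gene labels within comparisons (exhaustive enumeration replaces sampling
automatically when `(n!)^k` is small, used by the tests); the p-value is
the fraction of null rank products at most the observed one, and FDR at a
gene's cut is expected false positives (`p·n`) over observed positives,
made monotone by the step-up minimum.  Significance additionally requires
|mean log2 FC| > 0.6 — the fold-change cut-off is interpreted on the log2
scale (≈ 1.5-fold), recorded as a configurable since the original scale is
not stated.

qPCR relative expression is `R = x_t/x_r` on the efficiency-corrected
`E^(−Ct)` scale with first-order error propagation
`se_R = R·√((se_t/x_t)² + (se_r/x_r)²)`.

## Genetics

Seed-class expectations are exact rational probabilities from enumerating
parental gamete combinations under independent segregation.  A
maternal-effect (imprinted) requirement is evaluated on the maternally
transmitted allele only — encoded as a predicate flag, not hard-coded
biology — so "devoid of FIS activity" is the maternal mutant allele, and
the selfed double heterozygote gives exactly 1/8.

## Synthetic data: what it emulates and what it does not

Defaults define the study conditions: a 3×400-kb genome with central
heterochromatic blocks (20% of each chromosome); 300 genes, 30 pseudogenes,
150 TEs, 40 TEGs with heterochromatin bias 0.16 for TEs and 0.46 for TEGs
(the probed-genome fractions the study reports); ~35-bp jittered probe
tiling with 25-bp probes; 40 enrichment domains (30 over gene bodies, 10
over TE/TEG elements, ≥ 600 bp so minRun is exercised on both sides,
≥ 2 kb apart so each maps to one call) at effect 2.0 standardized-score
units on the IP channel only; Gaussian probe noise with SD 1.0 so raw
log2 effects equal standardized effects; three replicates per channel.
The reference list contains 86.5% of true targets plus 30% of non-target
gene-like features.  Methylation means per (class, context, tissue) encode
the contrast structure (shared ≈ 0.02 CG in both tissues; specific 0.65
vegetative / 0.30 endosperm; CHH ≤ 0.04 everywhere), with Beta-distributed
element levels (concentration 120) and binomial counts at Poisson ~50
coverage.  Expression: baselines N(6, 2), replicate noise SD 0.4, 2% of
genes deregulated at log2 effect 2.0 in the mutant.

Not emulated: probe sequence composition (the affinity covariate replaces
it), cross-array normalization artifacts, bisulfite reads (levels are
emitted as weighted fractions), spatially structured noise, and the
external methylome/expression compendia.  Passing tests demonstrate that
the algorithms recover what the generator embeds under realistic
signal-to-noise; they do not certify performance on real arrays with
sequence-driven probe effects.

## Problem sizes and numerical choices

The bundled genome (~34k probes, 520 features, 40 domains) keeps a full
pipeline run under ~2 s and the complete test suite under a minute; the
statistical calibration checks use 2000 genes × 3+3 replicates with 1000
permutations, 2000 null overlap draws, and 100-seed null batteries.  Scale
floors guard degenerate standardization bins (all-equal values give t = 0);
empty windows cannot occur (the focal probe is always in its own window);
quantile bins collapse with a warning when probes are fewer than bins; ties
in k-means on identical rows are resolved by the fixed seed.

## Known limitations

Cross-study target matching is id-level (no coordinate lift-over); the
methylation module takes a single vegetative table rather than merging
multiple source profiles; region calling has no FDR-calibrated or
replicate-consistency mode (the fixed 3.5 threshold is the method being
reproduced); and the boundary resolution analysis above bounds what any
caller can achieve at these probe densities.
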