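# Methods

## Coordinate conventions and interval operations

All coordinates are 0-based half-open (BED convention); GTF-style input
would need conversion on read. Two intervals overlap iff they share a
chromosome and `max(starts) < min(ends)`, so book-ended intervals do not
overlap; merging nevertheless joins book-ended intervals, matching
`bedtools merge` at distance 0. Intersection follows `bedtools intersect
-wa` semantics: a query overlapping any subject by at least 1 bp is reported
whole, never clipped. Binning tiles each chromosome as
`[0,w), [w,2w), …` with the final bin truncated at the chromosome end; bin
indices run consecutively across chromosomes in genome order. These
primitives are tested against per-base boolean-mask oracles on small
genomes.

## Annotation

Regions are assigned a single category at their midpoint with precedence
promoter > TTS ("other") > gene body > intergenic. The promoter window is
TSS −1000/+100 bp and the TTS window TES −100/+1000 bp, strand-aware and
clipped to chromosome bounds; both are configurable, and these defaults are
package choices in the spirit of HOMER-style annotation, not values dictated
by any single data set. Midpoint assignment (rather than fractional overlap)
guarantees an unambiguous single label per region. When several genes'
windows cover the midpoint, the gene with the smallest |TSS distance| wins,
with lexicographic gene id as the final tie-break, so annotation is fully
deterministic. A direction's "annotated gene list" is the deduplicated set
of genes from regions labelled promoter, gene body or TTS; intergenic
regions contribute no gene.

## Differential engine

The per-feature model is a two-group negative binomial with
`var = μ + α μ²`:

* **Size factors** — median-of-ratios: the reference is the per-feature
  geometric mean over features with all-positive counts; a sample's factor
  is the median of its count/reference ratios. The median is taken on the
  ratio scale (this matters only when the reference set has an even size).
* **Dispersion** — method of moments on normalized counts pooled within
  groups: `α = max(α_min, (v − μ)/μ²)` with `μ` the grand within-group mean
  and `v` the pooled within-group variance (df = samples − groups);
  `α_min = 1e-8`.
* **Wald test** — group rates by the ratio estimator
  `q_g = Σ K / Σ s` (pseudocount 0.5 added to a zero numerator), standard
  error of the log rate difference from the NB Fisher information
  `I_g = Σ_j μ_gj/(1 + α μ_gj)`, normal reference distribution, BH
  adjustment within each contrast's tested (post-filter) feature set only.

Deliberately omitted: fold-change shrinkage, Cook's-style outlier handling,
independent filtering, multi-factor designs. The aim is correct
direction/threshold behaviour with transparent arithmetic, not numeric
parity with a full GLM engine. Measured behaviour at the test suite's
conditions: null type-I ≈ 0.075–0.080 at nominal 0.05 (20 000 NB features,
dispersion 0.05, mean 50, 6 vs 6 — the plug-in dispersion and normal
reference make the test slightly anti-conservative at finite n), and
sensitivity ≈ 0.99 for |log2FC| = 2 spikes at mean 100 with 3 replicates per
group under FDR < 0.05, |log2FC| > 1. With only 3 replicates per group the
inflation is larger (≈ 0.12 at mean 200), which dilutes raw-p expression
call sets accordingly; both figures are recomputed by the suite and the
acceptance script.

All thresholds are strict inequalities (`q < 0.05`, `|log2fc| > 1`), so a
feature exactly at a boundary is not called. Expression contrasts use raw
p < 0.05 with no fold-change floor; the asymmetry against the DRIP FDR mode
is intentional and mirrors common practice for the two assay types.

## Region pipeline

Fragments are counted once each, into the bin containing the fragment
midpoint (`floor((start+end)/2)`) — no double counting, totals conserved.
The replicate filter keeps a bin iff *every* replicate of at least one of
the two contrasted groups has count strictly above the threshold (default
20). Validation is direction-aware: up (accumulated) bins must overlap the
merged peak set of the condition in which signal is higher, down (depleted)
bins the opposing condition's peaks; peaks from replicates are merged per
(genotype, condition) before use. Adjacent significant bins are *not*
merged into wider regions before counting — region counts are bin-granular.

## Integration and perturbation classifications

A gene's R-loop direction is "accumulated" if it hosts ≥ 1 validated
accumulated region (likewise depleted); a gene hosting both directions
contributes to both summaries, so counts are not additive across
directions. Concordance percentages use the DE genes among hosts as the
denominator (the pie-chart convention). The six response groups partition
genes DE in either of two genotypes by direction (A-only up/down, shared
up/down, B-only up/down); genes moving in opposite directions in the two
genotypes are quarantined in a separate `discordant` set and belong to no
group, which is why per-figure totals need not sum.

A region is *dampened* under a perturbation iff its perturbed-contrast
log2FC is strictly smaller than its reference-contrast log2FC
(`lfc_pert < lfc_ref`, i.e. `delta = lfc_ref − lfc_pert > 0`); equality is
not dampened. Classification is invariant to adding a common constant to
both columns. Regions missing from the perturbed table are an error by
default; an opt-in `assume_null` mode scores them as `lfc_pert = 0`
(coverage mismatches between contrasts are otherwise silent data loss).
Cross-treatment consistency tiers reference-significant regions by their
behaviour in a second treatment: significant-consistent
(same-direction log2FC beyond the floor and q below the FDR cut),
nonsignificant-consistent (same direction only), nonconsistent (opposite or
zero); the three fractions sum to 1 per direction. Effect correlation is
Pearson's r of two contrasts' log2FC over a region set, with the two-sided
t-transform p (n − 2 df).

## Enrichment

Over-representation uses the hypergeometric upper tail
`p = P(X ≥ k)` for overlap k between the query and a term, against a fixed
background universe, BH-adjusted within the tested term family; query genes
outside the background are dropped (logged). The Jaccard index
|A∩B| / |A∪B| compares enriched-term sets (q < 0.05), defined as 0 when both
sets are empty. No ontology-graph propagation or term clustering is
attempted.

## Synthetic data generator

The generator emulates a two-genotype (control C, mutant AT), four-condition
(UT, IR, H2O2, RNase-H1-overexpressing IR) design with 3 replicates per
group, and is the ground truth for every recovery test.

* **Genome and genes** — two 1.5 Mb chromosomes, 500 bp bins, 250
  non-overlapping genes of 4–12 kb with 1–3 kb gaps, random strands. These
  sizes keep a full study under a couple of seconds while leaving thousands
  of null bins per contrast.
* **True regions** — unions of 1–3 whole bins, non-overlapping, 70%
  intragenic (interior to a gene) and 30% intergenic (clear of any gene
  ±2.5 kb). Defaults: 80 up / 30 down for the genotype baseline contrast and
  120 up / 60 down for the treatment contrast, |log2FC| uniform on [1, 3].
  Within one contrast a gene hosts regions of a single direction. The
  effect-size distribution is a calibration choice for recovery tests, not
  an empirical claim about real R-loop changes.
* **Effect structure** — mutant treatment effects are the control effects
  scaled on the log scale by the attenuation a (default 0.4); RNase-H1
  effects are the matching IR effects scaled by the suppression σ (default
  0.3); the chemical (H2O2) contrast shares the IR truth exactly and
  differs only by sampling noise, which is what makes the effect-correlation
  mirror meaningful. The genotype effect is carried by all mutant samples,
  so it cancels in within-genotype contrasts.
* **Counts** — NB via the gamma–Poisson mixture with dispersion 0.05,
  baseline bin mean 60 (× enrichment 4 inside any true region, so true bins
  clear the replicate filter), per-sample library factors uniform on
  [0.7, 1.3]. Expression counts use lognormal per-gene baselines
  (median 200, σ_log = 0.5) and the coupled gene effects: each intragenic
  region's host gene is DE in the same direction with probability ρ = 0.7,
  plus 40 unrelated DE genes per contrast.
* **Peaks** — each replicate's peak set is the true-region footprint minus
  per-interval false-negative dropouts (5%) plus false-positive decoys
  (binomial, 5%) placed on bins outside the footprint.
* **Fragments** — per-bin Poisson draws with midpoints uniform in the bin;
  fragments have the configured length (300 bp) except near chromosome
  edges, where they shrink symmetrically so the midpoint rule inverts the
  draw exactly.
* **Term map** — a synthetic GMT: random terms plus a few "response" terms
  drawn 90% from coupled host genes of the baseline, IR, or both contrasts,
  so enrichment and term-set Jaccard have signal to find.

All randomness flows from one seed through labelled substreams
(`default_rng([seed, crc32(label)])`), so adding an output never perturbs
the others and identical config+seed gives byte-identical files.

What the simulation does *not* emulate: sequence content, GC or mappability
bias, fragment-level read noise, input-track subtraction, peak-caller
artifacts beyond uniform FN/FP, correlated dispersion across bins, and
realistic gene-length effects on expression counts. Passing recovery tests
therefore demonstrates that the pipeline's inference and classification
logic is correct under its own model assumptions, not that real DRIP-Seq
data meet those assumptions.

## Pipeline and reproducibility

`run_pipeline` executes a fixed plan over whatever sample groups the design
provides: baseline genotype contrast (|log2FC| > 1), IR/H2O2/RNase-H1
treatment contrasts per genotype (|log2FC| > 1.5), raw-p expression
contrasts, peak validation, annotation, concordance, response groups, Venn
partitions, dampened-region and gene-sensitivity classification, consistency
tiers, effect correlation, and enrichment with a Jaccard matrix. Every stage
writes TSV/BED/JSON artifacts and a manifest with row counts; the engine is
deterministic given inputs, so repeated runs are byte-identical. For the
dampened-region and consistency analyses, regions absent from the second
contrast's post-filter table are excluded from the classified set (the
pipeline's choice; the operators themselves error on missing regions unless
`assume_null` is requested).

`scripts/acceptance.py --seed N --out file.json` runs the default-condition
study end to end plus the engine calibration (20 000-feature null, 10 000-
feature power simulation) and reports every measured quantity as JSON;
problem sizes are the defaults above, chosen so the whole script completes
in seconds.

## Known limitations

* The Wald test is anti-conservative at small replicate numbers (see
  figures above); interpret raw-p expression calls accordingly.
* Dispersion is per-feature method-of-moments with no shrinkage, so it is
  noisy at n = 3; the FDR+fold-change combination compensates in practice.
* Midpoint annotation ignores partial overlaps; a region straddling a gene
  boundary is classified by its midpoint alone.
* The simulator's peak model is interval-level, not signal-level; validation
  FN/FP rates are uniform rather than coverage-dependent.
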