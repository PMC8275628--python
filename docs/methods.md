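# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data generator does and does not
emulate.

## Pipeline

### QC filter cascade

Four steps applied in a fixed order, with the defaults used throughout:

1. nuclei kept if the ERCC read fraction is strictly between 0.05 and 0.90;
2. nuclei kept if the number of endogenous genes detected is strictly
   between 1000 and 7000;
3. endogenous genes kept if detected in ≥ 25 of the surviving nuclei **and**
   carrying ≥ 250 total reads (an OR-combination of the two criteria is
   available via `QCThresholds.gene_filter_mode`); ERCC features are never
   removed by the gene filter;
4. nuclei kept if genes detected < 7000 and library size within
   [10 000, 300 000] inclusive.

Nucleus-level metrics are computed once on the input matrix and reused by
every nucleus step: the gene filter does not retroactively change a
nucleus's detection count or library size. Library size counts all mapped
reads including ERCC (configurable to endogenous-only). The cascade is a
fixed point on realistic data (re-applying it changes nothing); on
adversarial inputs a second pass could in principle remove more genes
because step 4 shrinks the nucleus set after the gene statistics were
computed — this is inherent to the stated step order, not an implementation
accident.

### ERCC normalization

Size factors are per-nucleus ERCC totals over the mean within the nucleus's
dilution group (two groups, 1:100 000 and 1:300 000), so they average to 1
per group; nuclei with zero ERCC reads are an error (they cannot pass QC).
Normalization divides counts by gene length in kb and rescales each nucleus
so that its length-normalized total equals `10000 · sf_i` — this identity is
exact (float tolerance 1e-8 relative in tests) and is the normalization's
contract. Cells with a length-normalized total above 50 000 are then
removed, values are log(1+x)-transformed, and ComBat (scanpy's parametric
empirical-Bayes implementation) can correct plate effects. ComBat is off by
default: the generator plants no plate effect, and the correction only
matters for real multi-plate data. The empirical-Bayes adjustment preserves
per-gene overall means only approximately (observed ~1e-3 on planted-offset
simulations); tests assert preservation at 0.01 absolute. Gene lengths are
taken from the feature table; for real data they should be derived
externally (e.g. union-exon length from a GTF).

### Clustering and annotation

PCA (50 components) → kNN graph (k = 15, Euclidean in PC space) → Leiden at
resolution 1.0, seeded. Leiden is used as the modularity optimizer because
it is the maintained successor of Louvain and optimizes the same objective.
Clusters are annotated by marker panels (six liver cell types, three
markers each, shipped as editable YAML): per cluster, the mean z-scored
expression of each panel is computed and the maximal panel wins; ties leave
a cluster `unassigned`. This replaces manual inspection of top DE genes
with a deterministic, testable rule. Caveat: if hepatocytes split into
strongly zonated subclusters, a pericentral hepatocyte marker (Cyp27a1) can
depress the hepatocyte score of periportal subclusters; with the default
panel and data this does not occur, but bespoke panels should avoid heavily
zonated markers.

### Ploidy contrasts

Welch's unequal-variance t per gene on log values, vectorized, with
Welch–Satterthwaite degrees of freedom; genes with zero variance in both
groups get t = 0, p = 1. The fold change is computed on back-transformed
group means, `log2((expm1(m̄_a)+ε)/(expm1(m̄_b)+ε))` with ε = 1e-9,
matching the convention of the rank-based Smart-seq tooling this follows;
calls require |log2FC| > 0.5 and Bonferroni-adjusted p < 0.05 (n tested =
genes in the matrix). The KS test uses scipy's two-sample implementation
(`method="auto"`: exact for small samples, asymptotic otherwise) on
log-normalized values; the shift rule is D > 0.15 ∧ p < 0.05. The
detected-gene fold is a ratio of group medians of per-nucleus detection
counts on the raw count matrix. The MA table restricts to genes with mean
back-transformed expression in [0.1, 100].

### Variability

Per-gene CV = sample sd (n−1) / mean of log values within a group, genes
with zero group mean excluded; groups are compared on the shared gene set
by the ratio of median CVs and a two-sided Mann–Whitney U across genes.
HVGs: per-gene dispersion (variance/mean of log values) is z-scored within
20 mean-quantile bins and the top 10% of positive z-scores are selected.
Binning is essential — raw variance residuals around a fitted trend are
heteroscedastic in the mean and would select only abundant genes. Because
the HVG rule is a per-group top-fraction, HVG *counts* are nearly equal
between groups by construction; the discriminating statistic for
ploidy-dependent variability is the CV ratio, not the HVG count.

### Stem-marker co-expression

Binarization is `value > 0` on log-normalized values, so "expressed" means
"detected". After restricting to the 10-marker stem panel, nuclei
expressing none of the markers are dropped. Jaccard similarity is computed
on nucleus index sets; a marker detected in zero retained nuclei gets J = 0
against all others (warning) and J = 1 with itself. Modules are flat
clusters (size ≥ 2) from cutting the average-linkage tree on 1−J at 0.5;
linkage method and threshold are configurable (single/complete/average).
Average linkage is the default because single linkage chains and complete
linkage over-fragments sparse detection patterns.

### Zonation

All zonation steps run on the z-scored, marker-restricted log expression
(8 zonated panel genes). Zone clusters: Leiden with the resolution bisected
in [0.01, 4] until exactly 3 communities emerge (k-means fallback if the
bisection fails); 3 matches the structure of the lobule analysis this
mirrors (one pericentral, two periportal communities). CV/PV annotation
compares mean z-scored pericentral vs periportal scores per cluster; exact
ties are an error. Diffusion pseudotime: kNN graph (k = 15) → diffusion
map → dpt from a root nucleus. The root is placed at the pericentral
extreme of the *leading diffusion component* (oriented by its correlation
with the pericentral-minus-periportal score) rather than at the nucleus
with the maximal raw marker score: the raw score is noisy and occasionally
puts the maximum mid-lobule, and a mid-lobule root folds the ordering.
Pseudotime is min-max rescaled to [0, 1], 0 at the CV end. Ploidy
enrichment defaults to the ratio of CV-assignment fractions, (4n in
CV / all 4n) ÷ (2n in CV / all 2n); an alternative against the overall CV
fraction is available (`mode="vs_overall"`). Bins are 10 equal-width
intervals of [0, 1]; empty bins report NaN. The zonation×ploidy
intersection takes the significant CV-up (PV-up) genes of the
all-hepatocyte CV-vs-PV contrast as the marker universe and reports those
significant in only one ploidy stratum; strata with fewer than 10 nuclei
per zone are skipped with a warning.

## Synthetic data

The generator emulates a plate-based snRNA-seq experiment on FACS-gated
liver nuclei at a desk-scale problem size: ~1,200 nuclei × 3,000 endogenous
genes + 92 ERCC species, six cell types (800 hepatocytes split 2n/4n, 400
others, all 2n). Defaults were chosen once to mirror the study conditions
and magnitudes:

- **Counts.** Endogenous counts are negative binomial with per-gene base
  means ~ LogNormal(log 1.5, 1.8) and per-nucleus capture efficiency
  ~ LogNormal(0, 0.3); dispersion θ = 2.0 for 4n and θ = 2.0/1.5 for 2n
  (diploid nuclei 1.5× more dispersed, the planted variability effect).
- **Detection fold.** A single 4n mean multiplier is solved numerically
  from the closed-form NB detection probability
  P(X>0) = 1 − (θ/(θ+μ))^θ so that the *expected* number of detected genes
  in 4n is 1.25× the 2n expectation. The multiplier is a model-derived
  calibration, not a fitted constant (≈ 2.3 under the defaults).
- **ERCC.** 92 species with relative concentrations log2-spaced over a 2^20
  range (a synthetic stand-in for the commercial mix — only relative
  abundances matter); Poisson counts with per-group amplitudes 18 000 and
  6 000 expected reads (3× apart, matching the 1:100 000 vs 1:300 000
  dilutions), scaled by the nucleus's capture efficiency so the ERCC
  fraction is efficiency-independent.
- **Zonation.** Each hepatocyte has a lobule coordinate z ∈ [0, 1].
  Pericentral/periportal genes scale as exp(∓slope·(z−0.5)); 120 CV and
  80 PV anonymous genes with slopes U(1, 2.5), plus 15 genes zonated only
  in 4n and 8 only in 2n. The named panel genes get means U(80, 300) and
  slope 2.5 — the high-abundance, steeply zonated regime characteristic of
  genes like Alb and Cyp2e1.
- **Ploidy placement.** 2n coordinates are uniform; the 4n density equals
  1.3× the uniform density everywhere below z = 0.7 (deficit in the far
  periportal tail). This makes the planted pericentral enrichment exactly
  1.3 for *any* empirical CV boundary at or below 0.7, so the planted value
  is well-defined regardless of where the data-driven zone clustering puts
  the boundary.
- **DEGs.** 40 genes up and 20 down in 4n at 4-fold. Planted effects (DEGs,
  zonated genes, cell-type programs) are placed only on genes with base
  mean ≥ 0.5: an effect planted on a gene that cannot pass the 25-nuclei /
  250-reads gene filter would be unrecoverable by construction.
- **Stem module.** Marker detection in hepatocytes is Bernoulli: a shared
  latent factor (p = 0.6) switches the six module markers between detection
  probabilities 0.8 and 0.05; non-module stem markers detect independently
  at 0.15. Detected marker counts scale with efficiency and the 4n global
  multiplier like every other transcript, so the module is
  ploidy-neutral after normalization.
- **Cell types.** Each type boosts its three named markers 8× and a private
  60-gene program 6×; cell-type markers draw base means from U(3, 10) so
  that a marker is always detectable (a marker lost to the gene filter
  cannot annotate).
- **Technical replicates** are re-sequenced copies (fresh counting noise,
  same latent state) of the first nuclei, flagged for removal. Plates (4)
  are assigned round-robin within each cell-type×ploidy block so ploidy is
  not confounded with plate or dilution; no plate effect is planted by
  default.

What the generator does **not** emulate: ambient RNA and doublets, gene
length–dependent coverage bias, intron/exon structure, batch effects beyond
the optional additive plate offset, cell-cycle signal, binucleation (ploidy
is a nucleus-level label; binucleated 2n×2 cells are indistinguishable from
2n by design), and any real gene-gene correlation beyond the planted
module, programs and gradients. Passing the recovery tests therefore shows
that the pipeline's statistics recover planted effects under NB noise at
realistic depth — not that they are robust to every artifact of real data.

## Evaluation conventions

Planted-DEG precision/recall are computed on the zonation-unconfounded gene
universe (genes with no planted gradient, stem markers excluded): genes
zonated in a ploidy-biased lobule genuinely differ between 2n and 4n in the
marginal contrast, so counting them as false positives would misattribute a
property of the planted biology to the DE machinery. Pseudospace fidelity
|Spearman ρ(dpt, z)| is measured on nuclei that truly are hepatocytes (a
stray non-hepatocyte in the cluster has no lobule coordinate). The
KS-shifted fraction between 2n and 4n is large (~0.6) on default data: the
planted global detection increase genuinely changes most genes'
zero-inflation, which is exactly what the distribution-shift rule detects.

## Problem sizes and determinism

Default analyses run on the ~1,200×3,000 simulation in a few seconds per
stage; the recovery evaluation uses ten seeds of the full pipeline and the
null calibration uses 2,000 genes × 150 nuclei per group × 10 replicates.
Every stochastic step (generator, PCA, neighbors, Leiden, diffusion map)
takes an explicit seed; a fixed seed reproduces byte-identical outputs.
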