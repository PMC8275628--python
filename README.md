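# hepatoseq

Downstream analysis of ploidy-resolved single-nucleus RNA-seq of the mouse
liver. Hepatocytes are naturally polyploid: nuclei FACS-gated by DNA content
(2n, 4n, and higher) can be profiled individually with deep plate-based
(Smart-seq-style) sequencing and ERCC spike-ins, which makes it possible to
ask how genome copy number and position along the liver lobule each shape
the transcriptome. This package implements the full post-alignment pipeline
for such data — QC, spike-in normalization, clustering and annotation,
ploidy contrasts, binary co-expression modules, and pseudospatial zonation —
together with a synthetic-data generator that plants every effect the
pipeline is designed to detect, so the whole analysis is testable end to end
without any external download.

It is aimed at computational biologists analysing plate-based snRNA-seq of
liver (or any tissue where a continuous spatial axis and a discrete gate
such as ploidy interact).

## The model

**ERCC size factors and normalization.** Within each spike-in dilution
group, the size factor of nucleus *i* is its total ERCC read count divided
by the group mean, so mean(sf) = 1 per group. Expression is normalized per
gene length and coverage:

```
x'_ij = (x_ij / L_j) / ( Σ_j (x_ij / L_j) / (10000 · sf_i) )
```

with `L_j` the gene length in kilobases. The per-nucleus identity
`Σ_j x'_ij = 10000 · sf_i` holds exactly and is asserted by the tests:
coverage differences are removed while ERCC-calibrated differences in
transcript content (e.g. between ploidy classes) are retained. Values are
then `ln(1+x)`-transformed (optional ComBat plate correction).

**Ploidy contrasts.** Per gene: Welch's *t* on log values with
`log2FC = log2((expm1(m̄_4n)+ε)/(expm1(m̄_2n)+ε))`, Bonferroni adjustment,
and a call rule of |log2FC| > 0.5 ∧ p_adj < 0.05; a two-sample
Kolmogorov–Smirnov test flags distribution shifts at D > 0.15 ∧ p < 0.05;
variability is the per-gene coefficient of variation of log expression,
compared between groups by the ratio of medians and a Mann–Whitney U test.

**Stem-marker co-expression.** Log expression is binarized (detected /
not detected), restricted to a stem/progenitor panel (*Icam1, Afp, Sox9,
Epcam, Axin2, Tbx3, Itga6, Tert, Lgr5, Notch2*), and marker co-detection is
scored by the Jaccard index `J(X,Y) = |X∩Y| / |X∪Y|` over nucleus sets;
modules are flat clusters of the average-linkage tree on `1−J`.

**Zonation.** On a panel of pericentral (*Cyp2e1, Gsta3, Cyp27a1, Mup17*)
and periportal (*Alb, Cyp2f2, Asl, Gls2*) markers: Leiden communities are
annotated CV/PV by z-scored marker scores, diffusion pseudotime from the
pericentral end of the manifold gives a pseudospace coordinate in [0, 1],
and on top of it the pipeline measures the relative enrichment of 4n
hepatocytes in the pericentral cluster, 10-bin marker profiles, and CV/PV
differential expression stratified by ploidy.

## Worked example

`analysis/` contains numbered drivers that run the pipeline on the default
synthetic dataset (seed 1) and write tables under `results/`:

```
$ python analysis/01_simulate.py
simulated 1202 nuclei x 3092 features (92 ERCC species)
planted: 60 DEGs, 231 zonated genes, 4n detection scale 2.27 (target fold 1.25),
pericentral 4n enrichment 1.3

$ python analysis/04_ploidy_contrasts.py
median detected-gene fold (4n / 2n): 1.247
DE genes: 53 up in 4n, 20 down in 4n of 2720 tested

$ python analysis/07_zonation.py
relative enrichment of 4n hepatocytes in the pericentral cluster: 1.15
zonation markers: 100 CV-up overall (16 only in 4n), 101 PV-up overall (11 only in 2n)
```

Reading these numbers: the generator planted a 1.25-fold detection increase
in 4n nuclei and the pipeline measures 1.247 from raw counts; of the 60
planted ploidy-DEGs, 53 + 20 calls are made (the handful of extra calls sit
on zonated genes, which really do differ between ploidies because 4n
hepatocytes are planted pericentrally — the zonation–ploidy crosstalk the
last stage then quantifies as a 1.15× pericentral enrichment against a
planted 1.3×). The stem-module stage recovers exactly the planted
six-marker module (*Axin2, Tbx3, Lgr5, Itga6, Tert, Notch2*).

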