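# svpopgen

Population genetics of structural variants (SVs) in multi-population
cohorts, built around the analyses used to study high-altitude adaptation in
Qinghai–Tibetan Plateau cattle: building a nonredundant cohort SV catalog
from long-read call sets, scanning it for population differentiation,
finding SV hotspots, and classifying SVs introgressed from a donor species
(yak) into the target populations.

It is organised as an analysis project: the library under `src/svpopgen/`
holds every computation, the numbered drivers under `analysis/` run the
stages end to end on a built-in synthetic cohort, and `scripts/acceptance.py`
re-measures the headline quantities from scratch.

## What it computes

**Catalog construction** (`svpopgen.catalog`). Per-sample calls from
multiple SV callers are reduced to a ≥2-caller consensus, then merged across
samples by single-linkage clustering of same-type calls whose breakpoints
both lie within 500 bp. The merged catalog is classified by sample sharing
(shared / major ≥ ⌈N/2⌉ / minor / singleton), annotated by genic region
(exonic > intronic > ±5 kb flank > intergenic), tagged as transposable-element
derived by ≥80% reciprocal overlap with a repeat track, and filtered for SVs
absent (all called genotypes 0/0) from the control populations.

**Differentiation scan** (`svpopgen.popgen`). Per-SV F<sub>ST</sub> uses the
Weir & Cockerham (1984) variance-component estimator

θ̂ = a / (a + b + c)

with a, b, c the among-population, among-individual and within-individual
components; windowed F<sub>ST</sub> (50 kb windows, 25 kb step) is the ratio
of sums Σa / Σ(a+b+c). The locus-level selection statistic sums the
genome-standardized pairwise F<sub>ST</sub> of the pooled target group
against each control population j:

d<sub>i</sub> = Σ<sub>j</sub> (θ̂<sub>ij</sub> − μ<sub>ij</sub>) / σ<sub>ij</sub>

and outliers are flagged by a one-sided Z test at α = 0.001 (critical
Z ≈ 3.09).

**Hotspots** (`svpopgen.hotspots`). SV midpoints are smoothed with a
Gaussian kernel (bandwidth 500 kb) on a 10 kb grid; the null re-places the
same number of midpoints uniformly per chromosome; grid points significant
after Benjamini–Hochberg are merged and extended by half a bandwidth.
Enrichment of an annotation inside hotspots is a Z test against either
random relocation of the hotspot intervals or random same-size subsets of
all SV midpoints.

**Introgression** (`svpopgen.introgression`). A candidate introgressed SV is
fixed among called donor genotypes, homozygous-reference in every called
control, and carried by at least one target sample. Each candidate is
validated on its 50-kb flanking SNPs: an allele-sharing (1 − IBS) distance
matrix feeds a neighbor-joining tree, and the call passes when some edge of
the tree separates carriers + donors from all non-carrier cattle.

**Synthetic cohorts** (`svpopgen.simulate`). Genotypes follow the
Balding–Nichols model (population frequencies Beta-distributed around an
ancestral frequency with drift parameter F), with planted position clusters,
frequency-shifted SVs, donor-fixed introgressions with donor-derived carrier
haplotypes, and TE labels enriched inside clusters — plus truth tables, so
every stage is testable without any download.

## Worked example

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/
python analysis/02_build_catalog.py
python analysis/03_selection_scan.py
python analysis/04_hotspot_scan.py
python analysis/05_introgression.py
```

With the default seed the drivers print:

```
simulated 6500 SVs (DEL=2710, INS=3427, DUP=189, INV=71, BND=103) across 71 samples
planted: 1500 cluster SVs in 5 clusters, 50 differentiated, 50 introgressed
...
pooled target-vs-control FST over 6500 SVs: mean theta = 0.0260, ratio-of-sums = 0.0296
di scan: 67 outliers at alpha=0.001 (1.03% of SVs)
against planted truth (50 shifted SVs): recall=0.88, precision=0.66
...
4 hotspots spanning 11.0 Mb (1828 of 6500 SV midpoints inside)
TE-derived SVs in hotspots: observed 968, null 516.5 +/- 15.8, Z = 28.57, p = 7.18e-180
conserved elements in hotspots: observed 116, null 145.7 +/- 11.9, Z = -2.48, p = 6.51e-03
...
candidates (donor-fixed, control-absent, target-carried): 50 of 6500 SVs (50/50 planted introgressions recovered)
NJ-tree validation on 50 flanking-SNP windows: 50 validated, 0 rejected, 0 without SNP data
```

Reading the output: the simulated cohort has modest genome-wide
differentiation (ratio-of-sums θ̂ ≈ 0.03 between pooled targets and
controls), the d<sub>i</sub> scan recovers 44 of the 50 planted
frequency-shifted SVs, the hotspot caller finds the planted midpoint
clusters (two adjacent clusters merge into one interval here), TE-derived
SVs are strongly over-represented inside hotspots while conserved elements
are depleted, and every planted donor introgression is both nominated by the
genotype rule and confirmed by its flanking-haplotype tree.

`svpopgen.pipeline.run_pipeline` runs the same stages from one `RunConfig`
(YAML-loadable) and writes per-stage TSVs plus a `summary.json`.

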