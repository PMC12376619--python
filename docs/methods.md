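# Methods

This note records the models, estimators and numerical choices behind
`svpopgen`, and what the synthetic cohorts do and do not establish.

## Data model and coordinate conventions

All internal coordinates are 1-based (VCF-native); BED input is converted at
the boundary and back on write. Span-type SVs (DEL/DUP/INV) follow the VCF
anchor-base convention that htslib enforces for symbolic alleles: `start` is
POS, `end` is INFO/END, and `svlen = end − start`, so END = POS + |SVLEN|
exactly. Insertions and break-ends are point events (`end = start`); an INS
`svlen` is the inserted length and a BND carries mate coordinates
(CHR2/POS2). SVLEN is stored unsigned and the deletion sign is re-applied
on write. Non-BND SVs must be ≥ 50 bp, the conventional lower bound for a
structural variant. Missing genotypes (`./.`) are a first-class state
excluded from every allele count.

## Catalog construction

Consensus and cross-sample merging both use single-linkage clustering: two
calls link when they share chromosome and type (and BND mate chromosome)
and both breakpoints lie within `max_breakpoint_dist` (default 500 bp).
Linkage is transitive, so chained calls merge even when cluster extremes
are farther apart — the behaviour of SURVIVOR-style merging; the distance
and a same-type requirement are configurable. The consensus representative
is the call from the first supporting caller in priority order; the merge
representative is the earliest sample in the configured order (leftmost on
ties), which keeps output ids stable for a documented order. Collapsing
near-duplicate records after genotyping is the same operation run at
distance 0.

Sharing classes use carrier counts (≥ 1 ALT allele): shared = all N
samples, major = ≥ ⌈N/2⌉ (84 samples → 42), singleton = 1, minor
otherwise; shared takes precedence over major. Region labels follow the
precedence exonic > intronic > upstream/downstream > intergenic, with a
5 kb flank window (the common annotator default; nothing in the analysis is
sensitive to it at the simulated gene density). TE tagging requires ≥ 80%
reciprocal overlap between a DEL/DUP span and a repeat interval; insertion
TE labels come from a sidecar table because classifying an inserted
sequence requires alignment of the sequence itself, which is out of scope.

## FST and the di statistic

Per-site FST is the Weir & Cockerham (1984) estimator for diploid data,
computed from per-population sample sizes, ALT frequencies and observed
heterozygosities; θ̂ = a/(a+b+c) with NaN at monomorphic sites. Negative
estimates are retained: clamping would bias the genome-wide moments used
below (clamping is available at report time). Windowed FST is the ratio of
sums Σa/Σ(a+b+c) — not the mean of per-site ratios — which weights sites by
information content. Populations with no called genotype at a site drop
out of that site's estimate; sites with fewer than two informative
populations are undefined.

The di statistic contrasts a focal group against each comparison population
j: di(s) = Σ_j [θ̂_j(s) − μ_j]/σ_j, with μ_j, σ_j the mean and sample SD of
θ̂_j across all SVs (undefined θ̂ excluded pairwise, with the contributing
pair count reported per SV). The default focal unit is the pooled target
group versus each control population separately; a per-target-population
mode is provided because the grouping convention differs between studies.
Outliers are called one-sided (elevated differentiation) with a Z test on
di at α = 0.001.

**Calibration caveat.** With only a handful of comparison populations, di
is *not* normal under the null: per-pair θ̂ is right-skewed (its
between-population variance term has r−1 = 1 degree of freedom for a pair),
and summing 2–4 strongly correlated skewed terms leaves skewness ≈ 1.6–2.
The one-sided normal test at α = 0.001 therefore flags ~1% of SVs on
label-permuted cohorts rather than 0.1%, independent of sample size. This
is a property of the statistic as defined, not of the implementation (which
matches an independently coded oracle to < 1e-10 on random configurations).
`di_outliers(method="empirical")` flags the top-α rank quantile instead and
is calibrated by construction; the Z test remains the default because it is
the form used in the field.

## Hotspot detection

Midpoints (floor of (start+end)/2; the position itself for point events)
are binned at the grid step (10 kb) and smoothed with a Gaussian kernel of
bandwidth 500 kb — with the permutation comparison below, only relative
density matters, so the unnormalized smoothed count is used. The null
re-places the same number of midpoints uniformly on the chromosome
(n_perm = 200). Null density values are pooled across grid points and
permutations of a chromosome before computing empirical p values with the
+1 pseudo-count convention: under a uniform null the smoothed density is
exchangeable across interior grid points, and pooling gives p-value
resolution ~1/(n_perm × n_grid) instead of 1/n_perm, without which
genome-wide Benjamini–Hochberg control (α = 0.05) could never fire at 200
permutations. Significant grid points are merged into maximal runs,
extended by bandwidth/2 per side (the smoothing radius), clipped to the
chromosome, and overlapping intervals merged. The bandwidth default gives
~Mb-scale hotspots, the scale reported for mammalian SV hotspot maps.

Enrichment uses observed = annotated points inside hotspots with two
exchangeable nulls. For *external* annotations (e.g. conserved elements)
the default relocates the hotspot intervals uniformly (lengths and
chromosome assignment preserved, non-overlapping), which preserves the
annotation's own clustering. For annotations that are themselves SV
subsets (TE-derived SVs) the subset null — random same-size subsets of all
SV midpoints — is used instead: hotspots are defined by elevated SV
density, so relocation conflates composition with density and would report
enrichment even for TE-depleted hotspots. Z = (obs − mean)/SD of the null
with a one-sided normal p in the deviation's direction.

## Introgression classification

A candidate is required to be (i) fixed among called donor genotypes
(ALT frequency ≥ 1.0 by default — a missing donor call does not break
fixation, which is the practical reading of "fixed in the donor" under
missingness), (ii) ALT-free among called controls, (iii) carried by ≥ 1
target sample, and (iv) genotyped in ≥ 80% of each role group. These strict
defaults implement the fixed/absent rule literally; under per-genotype
error ε the expected recall is bounded by (1−ε)^(n_donor+n_control), so
noisy cohorts need thresholds sized to the noise (e.g. donor ≥ 0.8,
control ≤ 0.08 restores recall ≥ 0.8 at 5% error in the test suite) — the
defaults are left strict deliberately.

Validation builds, per candidate, the allele-sharing distance
d(x,y) = 1 − mean IBS over jointly called flanking SNPs (IBS per site =
shared alleles / 2 ∈ {0, ½, 1}) and a neighbor-joining tree (Saitou–Nei,
via scikit-bio; exact on additive matrices). The call is validated when
some edge of the unrooted tree separates carriers ∪ donors from all
non-carrier cattle — operationally, the smallest bipartition side
containing every donor *and* every carrier contains no non-carrier cattle.
The donor-only clade may be a strict subset of that side: a heterozygous
carrier holds one donor and one cattle haplotype and therefore attaches as
sister to the donor clade, not inside it. Genotypes (not phased
haplotypes) feed the distance; allele-sharing distance is the standard
phase-free analog. The flanking window is two-sided
[start − 50 kb, end + 50 kb], clipped to the chromosome.

## Synthetic cohorts

The generator plants exactly the structure the stages are meant to detect.
Defaults mirror a plateau-cattle scan design: five target populations
(n = 10, 7, 10, 6, 3; 36 samples), four control populations (n = 10, 5, 7,
1; 23 samples) and a 12-sample donor species; 5,000 background SVs plus
5 clusters × 300 SVs on a 3 × 50 Mb genome; SV type mix DEL 0.403 /
INS 0.539 / DUP 0.029 / INV 0.012 / BND 0.017 (the empirical mix of a
222k-SV long-read cattle catalog); lognormal lengths (mode a few hundred
bp, capped at 100 kb).

Genotypes follow the Balding–Nichols model: ancestral frequency
p ~ U(0.05, 0.95) (bounded away from 0/1 to limit monomorphic draws;
residual monomorphic SVs are redrawn with capped retries), population
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with F = 0.1 by default, and
genotypes ~ Binomial(2, p_pop). This makes F recovery by the
Weir–Cockerham estimator a meaningful end-to-end check. Differentiated SVs
shift the target-side ancestral frequency by +Δ (default 0.6, capped at 1)
before the Beta draw. Introgressed SVs are set donor-fixed, control-absent
and target-segregating at carrier frequency c (allele frequency
1 − √(1−c)); their flanking windows hold two haplotype pools diverged at
per-site probability d = 0.2, per-haplotype mutation noise 0.02, with each
carrier receiving one donor haplotype. TE labels are drawn at 0.6 inside
planted clusters vs 0.2 outside (classes LINE 0.81 / SINE 0.107 /
LTR 0.072 / DNA 0.011, the LINE-dominated ruminant mix); matching repeat
intervals are emitted so the reciprocal-overlap tagger can recover the
labels from files. Conserved elements are placed with weight 0.3 inside
cluster regions to plant depletion. Genotype error (uniform state flips)
and missingness are applied last; both default to 0.

What passing these tests shows — and does not. The cohorts are
Hardy–Weinberg, linkage-free (each SV independent), with exchangeable
samples inside populations and no coalescent or recombination structure;
breakpoint uncertainty appears only as the jitter the catalog drivers add.
Results on real long-read cohorts additionally face reference bias, caller-
specific breakpoint error, segmental-duplication artifacts and LD between
SVs, none of which are modelled.

## Problem sizes and determinism

Everything derives from `numpy.random.default_rng` seeded per run; the
pipeline is a pure function of (inputs, config, seed), and identical seeds
give byte-identical outputs. Tests and the acceptance script run at
reduced but statistically adequate sizes chosen once: 5,000-SV cohorts for
frequency-based checks, 4,500 SVs for hotspot recovery, 500-SV cohorts
with 50 introgressions for the donor scan, 1,000 random configurations for
the estimator oracle, 100 random additive trees (n = 4–8) for NJ. Percent
summaries round half-even to 2 decimals; headline carrier rates are also
reported as integer percentages.
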