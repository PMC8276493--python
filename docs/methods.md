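# Methods

This note documents the statistical models behind `selsig`, the parameter
defaults and why they were chosen, what the bundled simulator does and
does not emulate, and the numerical conventions that matter when
comparing implementations.

## Coordinates and data model

Positions are 1-based inclusive everywhere inside the library (the VCF
convention); interval files written as BED use 0-based half-open
coordinates, converted only at the writer/reader boundary. Genotypes are
alt-allele dosages in {0, 1, 2} with −1 for missing. Multi-allelic VCF
sites are skipped rather than split: array data for this kind of
experiment is biallelic and splitting would add untested surface.
Imputation is deliberately not implemented; every statistic instead uses
per-SNP effective (non-missing) sample sizes.

## Quality control

Defaults mirror common livestock-array practice: individuals need a call
rate ≥ 0.97; SNPs need minor-allele frequency ≥ 0.05 and missingness
≤ 0.05, computed on the retained individuals (samples are filtered
first), with the minor allele defined per SNP across retained samples.
Filtering is idempotent on its own output.

## Runs of homozygosity

The caller is the classic SNP-count scanning-window algorithm.
Windows of 50 consecutive SNPs slide one SNP at a time; a window passes
with ≤ 1 heterozygote and 0 missing calls; a homozygous SNP qualifies
when ≥ 5 % of the windows covering it pass; maximal runs of qualifying
SNPs (split at > 1 Mb gaps) are ROH when they contain ≥ 50 SNPs at a
density of ≤ 30 kb per SNP. Two conventions worth noting:

- Windows are SNP-count windows only. The frequently quoted "500 kb"
  figure describes array density (~1 SNP / 10 kb), not a second
  constraint; the algorithm itself is SNP-count-driven.
- The homozygous-window fraction is 0.05 (5 %). Printed descriptions of
  this parameter sometimes read "0.05 %"; the literal 0.0005 is
  reachable through `ROHParams(min_hom_window_fraction=0.0005)` but the
  conventional default of the algorithm is 5 %.
- "more than 50 SNPs" is implemented inclusively (≥ 50) and can be made
  strict via `ROHParams(inclusive_min_snps=False)`.

Consensus regions are maximal runs of consecutive SNPs covered by ROH in
at least `min_count` (default 2) individuals, subdivided wherever the
per-line coverage profile changes. Each region therefore carries exact
HIGH/LOW coverage counts, and thresholding regions on those counts is
identical to evaluating the line-threshold predicate SNP by SNP. A
region qualifies as a signature when it reaches the threshold in *both*
lines — by default ⌈0.5 × line size⌉, with absolute thresholds available
to reproduce published cut-offs (e.g. 70/65). Region boundaries are
SNP-resolution (outermost qualifying SNP positions), not base-resolution
unions.

## Windowed Weir–Cockerham F_ST

Per SNP, the two-population variance components of the Weir–Cockerham
(1984) estimator are computed from (nᵢ, pᵢ, hᵢ): the per-line
non-missing diploid count, alt-allele frequency and *observed*
heterozygote fraction (no Hardy–Weinberg assumption). With
n̄ = (n₁+n₂)/2, n_c = 2n̄ − (n₁²+n₂²)/(2n̄), p̄ and h̄ the
sample-size-weighted means and s² the among-population variance:

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − s²/2 − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − s²/2 − h̄ (2n̄−1)/(4n̄) ]
    c = h̄/2

Components are NaN when n̄ ≤ 1 (no within-population degrees of
freedom). Window values are the ratio of sums Σa / Σ(a+b+c) over 500-kb
windows tiled from position 1 with 250-kb steps; windows with < 10
usable SNPs or a vanishing denominator are dropped, trailing partial
windows are kept if they qualify. Negative window values are retained —
the relevance threshold (genome-wide 99.9th percentile,
linear-interpolation definition, ties included) is taken over the
estimator's actual distribution.

### Drift versus selection

Relevant windows are classified by comparing each line to the base
population. Per SNP the *tracked* allele is the base-population minor
allele, so direction of change is comparable across cohorts. One further
re-polarization is applied before window averaging: each SNP is oriented
so that its base→HIGH change is non-negative. Minor/major folding is an
arbitrary per-SNP orientation, and under it the signed changes of ~50
linked SNPs cancel in the mean — a window over a genuine divergent sweep
averages to "no change". With a consistent orientation, parallel change
keeps the two lines on the same side of the base while divergent
selection drives them apart. The window-level rule on the aggregated
frequencies (Δh = f_HIGH − f_base, Δl = f_LOW − f_base, tolerance
ε = 0.01, for which no published value exists) is:

- |Δh| ≤ ε or |Δl| ≤ ε → DRIFT (one line did not move);
- sign(Δh) = sign(Δl) → DRIFT (parallel change);
- otherwise → SELECTION.

Windows with no SNP polymorphic in the base population are UNCLASSIFIED.
One honest caveat: conditioning on extreme F_ST favours windows where
the lines happen to sit on opposite sides of the base, so pure drift can
still produce SELECTION calls; the classification reduces, but does not
eliminate, drift false positives — which is exactly why the
generation-13 validation stage exists.

## varLD

For every window of 50 consecutive SNPs (step one SNP) the pairwise r²
matrix of each population is the squared Pearson correlation of unphased
dosage vectors (the composite-LD convention; phase is unknown on
arrays), over pairwise-complete samples. A monomorphic SNP gets zero
off-diagonal correlation and a unit diagonal — the alternative (dropping
the SNP) would misalign windows between populations. The raw score is
Σᵢ |λ₁,ᵢ − λ₂,ᵢ| over descending-sorted eigenvalues; scores are
standardized per chromosome with the sample standard deviation (n−1;
configurable). Trailing windows with fewer than 50 SNPs are dropped; a
chromosome whose scores are all equal standardizes to 0 with a warning.

Three comparisons are computed (Base–High, Base–Low, High–Low), each
ranked against its own genome-wide 99.9th percentile. Selection
intervals are the base-pair intersections (≥ 1 bp) of relevant Base–High
and Base–Low regions; drift intervals are relevant High–Low regions
overlapping neither.

## Validation and reporting

A putative interval becomes a *true* signature when the same method,
rerun in full on the base + generation-13 cohorts (thresholds recomputed
on the generation-13 distribution, fractional ROH thresholds recomputed
from the smaller cohorts), yields an overlapping interval (≥ 1 bp; no
published overlap rule exists, so the weakest criterion is used).
Validation never mixes methods. True intervals keep their generation-11
coordinates. Reports give per-method BEDs, their union, and the genes
whose annotated interval overlaps the union by ≥ 1 bp.

## Functional-variant prioritisation

Pooled whole-genome sequencing of each line is summarised as one
diploid-style consensus genotype per line with alleles 0 (reference),
1 (alternative) and 2 (novel allele absent from the reference assembly).
A variant is a transcription-unit functional mutation when any effect is
3'UTR, 5'UTR, missense, frameshift or splicing; stop-gained, start-lost
and inframe classes can be added via a flag but are off by default. The
fixed-divergent rule — both line genotypes homozygous with disjoint
allele sets — covers 1/1 vs 0/0 and 1/1 vs 2/2 and is symmetric in line
order. Effect tabulation counts (gene, class) occurrences, so a variant
annotated on two genes contributes two effects. The effect vocabulary is
fixed to 14 classes; a mapping from common annotator terms (e.g.
`3_prime_UTR_variant`, `splice_donor_variant`) is applied at load time,
and unknown classes are an error naming the offending string.

GO pathway percentages use case-insensitive substring matching of a
keyword dictionary against GO description strings (not ontology-graph
traversal): each description is assigned to the first matching pathway
in dictionary order (so percentages Xᵢ/N × 100 sum to 100), unmatched
descriptions fall into "Other Processes", and an optional multi-assign
mode lets a description count toward several pathways (sums may then
exceed 100).

## The simulator

`simdata` emulates the data-generating process of a two-line divergent
selection experiment, desk-scaled:

- **Base population.** SNP positions uniform (deduplicated, sorted);
  founder alt-allele frequencies from Beta(0.5, 0.5) conditioned on
  polymorphism among the founders; each base haplotype is a mosaic of a
  limited founder pool (default 30 haplotypes), with segment breaks from
  a Poisson crossover process (Haldane model, default 1 cM/Mb). The
  limited pool creates LD that decays with distance.
- **Lines.** Discrete Wright–Fisher generations of constant size
  (default 100 diploids per line). Parents are drawn multinomially with
  fitness multiplicative over selected loci, weights (1, 1+s, 1+2s) by
  favored-allele count; loci favoring the other line are neutral.
  A locus can favor the alt allele in one line and the ref allele in the
  other (`divergent_locus`), which is how a causal site behaves under
  divergent selection on a trait. Loci are pinned to the nearest
  simulated SNP and may be given an initial founder frequency
  (`init_freq`); a frequency of 1/n_founders puts the allele on a single
  haplotype background (hard sweep), 0.5 spreads it over many (soft
  sweep).
- **Cohorts.** Generations 0, 11 and 13 of one continuous simulation are
  sampled without replacement (defaults: 96 base animals, all 100 per
  line at generation 11, 46/49 at generation 13 — the reduced
  generation-13 cohort deliberately mirrors a validation dataset that is
  smaller than the discovery dataset). Everything is deterministic given
  the config seed.

Default scale is 2 chromosomes × 20 Mb × 2,000 SNPs (1 SNP / 10 kb, the
density the ROH defaults assume) — small enough that the full
three-method, two-generation pipeline runs in seconds while windows
still hold ~50 SNPs. Effective population sizes of real selection lines
are rarely published; 100 per line is a plausible order of magnitude for
a small-species selection experiment, not a calibrated value.

What the simulator does **not** emulate: mutation after generation 0,
overlapping generations, non-random mating, genotyping error,
array ascertainment bias, and any phenotype model (selection acts
directly on genotypes, not on a trait with environmental variance).
Passing tests therefore demonstrate that the statistics detect the
genomic footprints they target under idealised inheritance — not that
the pipeline is robust to array artefacts or to selection on a weakly
heritable trait.

The annotated-variant generator fabricates gene intervals and
effect-annotated variants with realistic class proportions (intergenic
and intronic classes dominate), plants a configurable number of
fixed-divergent functional INDELs, and guarantees every non-planted
record fails at least one filter criterion, so the planted truth set is
recoverable exactly.

## Numerical conventions and degenerate inputs

- Percentiles use numpy's linear-interpolation quantile; relevance is
  "value ≥ threshold" so ties at the threshold are included.
- Allele frequencies of SNPs with no called genotypes propagate as NaN,
  never as 0.
- θ per SNP is undefined (NaN) when a+b+c = 0 (shared monomorphism);
  such SNPs contribute nothing to window sums.
- Chromosomes with fewer SNPs than a window yield no windows (logged,
  not an error); an all-samples-dropped QC result is an explicit error.
- Eigenvalues come from the symmetric solver (`eigvalsh`); the varLD
  score is invariant to population order by construction.
- Sample standard deviation (ddof = 1) for varLD standardization.

## Problem sizes used by the test suite

Stochastic suites run at the simulator's default desk scale: 10
replicates for the neutral-drift calibration (mean windowed weighted
F_ST within ±25 % of 1 − (1 − 1/2N)^t) and for sweep recovery
(relevance + classification + generation-13 validation in ≥ 7 of 10
replicates), 100 small replicates for the Wright–Fisher variance check,
and 20 replicates for LD decay and the ROH brute-force equivalence.
These sizes keep the full suite under a few minutes while leaving the
Monte-Carlo bounds comfortably non-trivial.

## Known limitations

- The drift/selection rule's specificity under pure drift is limited
  (see above); treat SELECTION calls without generation-13 support with
  caution.
- ROH consensus thresholds assume roughly equal line sizes; severely
  unbalanced cohorts would need the absolute-threshold interface.
- varLD standardization needs ≥ 2 windows per chromosome; micro
  chromosomes should be excluded or merged by the caller.
- The PLINK dialect is the two-file PED/MAP text form with alleles in
  MAP columns 5–6 (a documented extension); binary BED/BIM/FAM is out of
  scope.
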