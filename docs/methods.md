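# Methods

## Problem setting

`glucovar` analyses biallelic variant panels from candidate pharmacogenes
(here: 18 genes of the glucocorticoid response pathway) in small cohorts,
and contrasts them with large reference panels. The motivating design has
seven populations — two indigenous Amazonian cohorts (5 individuals with
acute lymphoblastic leukemia, IND-LLA; 59 without, IND-NLLA) and the five
1000 Genomes continental panels (AFR 661, AMR 347, EAS 504, EUR 503,
SAS 489) — genotyped at ~253 variants. Cohort genotypes of this kind are
typically not redistributable, so the package pairs every analysis stage
with a synthetic generator and ships the study's printed summary tables as
fixtures for validation.

## Impact classification and summaries

Consequence labels form a closed 11-category set. The consequence → impact
mapping is:

| tier     | consequences |
|----------|--------------|
| High     | stop gained; protein structural interaction locus |
| Moderate | non synonymous coding; non synonymous coding + splice site region |
| Low      | synonymous coding; splice site region + intron; next protein |
| Modifier | intronic; intragenic; 3'UTR; 5'UTR |

The reference rendering of the panel never states this rule; it is fixed
by exactly reconciling the panel's two printed marginals (consequences vs
impact tiers: 1+5=6 High, 38+1=39 Moderate, 40+8+2=50 Low,
8+134+9+7=158 Modifier). Assigning "protein structural interaction locus"
to High is forced by that reconciliation. The mapping is total and raises
on unknown categories — no silent default tier. "Intron" and "intronic"
(and "stop codon"/"stop gained", primed UTR spellings) are treated as
spelling variants of one category.

Summary percentages are 100·count/total rounded **half-up** to one
decimal, computed on the exact rational value. The transcribed reference
rendering is internally inconsistent here: most of its percentages
(27/253 → 10.7, 8/253 → 3.2, 9/253 → 3.6, 1/253 → 0.4, 6/253 → 2.4,
50/253 → 19.8) require rounding up, while three (134/253 printed 52.9,
5/253 printed 1.9, 158/253 printed 62.4) match truncation only. Half-up is
adopted as the single consistent rule; the three truncated renderings are
treated as printing artefacts and are not reproduced.

## Inclusion filters and exclusivity

A genotype is *called* when its read depth is at least `min_coverage`
(default 10 reads); without a depth matrix, non-missing VCF genotypes
count as called (`./.` stands in for below-threshold coverage). A sample
is a *carrier* when called with dosage ≥ 1. A variant is retained when
carriers ≥ `min_carriers` (default 10, against a 64-sample cohort) **or**
when flagged novel (absent from previously reported populations) — the
novelty override is a plain OR, since group-private variants at carrier
counts as low as 1 must survive selection. "Presence in at least 10
individuals" is read as carrier count, not allele count; both the
threshold and the interpretation are configurable. The filter is monotone
in `min_carriers`.

Exclusivity: a variant is private to a target group iff alt_count > 0
there and alt_count = 0 with called_alleles > 0 in every reference panel.
A panel with zero called alleles at a site makes that variant
*unassessable* — it is flagged and never reported exclusive. The
deduplicated union across target groups is keyed by (chrom, pos, ref, alt).

## Standardized Fisher contrasts

Allele frequencies come from allele counting over called genotypes
(alt_count / 2·called samples). To neutralise cohort-size imbalance, both
sides of every contrast are standardized to a fixed allele total
(default 118): yes = round-half-up(AF × 118), no = 118 − yes. Rounding to
integers is required by the exact test; half-up is the stated convention
and conserves the total by construction.

The two-sided Fisher p uses the probability-mass rule: with margins
fixed, sum hypergeometric probabilities of all tables no more probable
than the observed one, with relative tolerance 1e−7 guarding float ties.
This is implemented directly (vectorised `hypergeom.pmf` over the
support) and is cross-checked in the tests against both exact
rational-arithmetic enumeration and `scipy.stats.fisher_exact`.

Hochberg step-up adjustment (adjusted(i) = min over j ≥ i of
(m−j+1)·p(j), capped at 1) is applied per variant across its comparators
by default; a `global` scope (one family across all tests) is available,
since the original correction scope is ambiguous. Direction signs are
sign(AF_reference − AF_comparator).

The reporting rule selects variants with p < α (default 0.05, raw p by
default — the reference tables do not state whether their p-values are
adjusted, so both are emitted) in at least `min_populations` (default 3)
of the comparisons, with impact tier in {High, Moderate}. Everything else
is routed to a supplementary table.

## Divergence

*MDS* operates at population level: profiles are population × variant
allele-frequency matrices (unobserved cells filled with 0, logged), with
euclidean (default), manhattan or Bray–Curtis distances. Classical
(Torgerson) MDS double-centres the squared distances
(B = −½·J·D²·J), eigendecomposes B, and scales eigenvectors by the square
roots of their nonnegative eigenvalues; eigenvalues are reported in
descending order, axes are truncated (with a warning) when fewer positive
eigenvalues exist than requested, and each axis is oriented so its
largest-magnitude loading is positive, for platform-stable output.

*PERMANOVA* operates at individual level (entities = samples, distances
over dosage vectors), because the reference results' F and R² are
mutually consistent with df = n−2 at the study's sample sizes only under
individual-level analysis. Sums of squares follow the standard
inter-point form (SS_T = Σ_{i<j} d²/N; SS_W summed per group with 1/n_g
weights); p-values use the add-one permutation estimator with
`n_permutations` = 999 by default, so p ≥ 1/(n_perm+1) always. For two
groups the permutation null is evaluated as quadratic forms of group
indicators in the squared-distance matrix — one matrix product for all
permutations — and the observed grouping is pushed through the same
arithmetic so exact relabeling ties compare equal. Pairwise mode runs one
two-group test per pair on the restricted sub-matrix, with an independent
child seed per pair and Hochberg adjustment across pairs. Missing dosages
in distance computation are handled pairwise-complete with rescaling by
the fraction of features used.

The packaged pairwise-PERMANOVA reference table reports p = 0.006 for all
significant rows; that value is not derivable from any stated permutation
count or correction scope, so the package reports its own raw and
adjusted permutation p-values and makes no attempt to match it. The
reference table is instead validated through the F = R²(n−2)/(1−R²)
consistency identity at the study's group sizes.

## Synthetic generator

Balding–Nichols per locus: ancestral frequency p ~ Uniform(0.05, 0.95)
(bounded away from 0/1 so monomorphic loci do not dominate), population
frequency q ~ Beta(p(1−F)/F, (1−p)(1−F)/F) — mean p, variance F·p(1−p) —
with F = 0 degenerating to q = p exactly. Genotypes are Binomial(2, q)
dosages; missingness is genotype-wise i.i.d. (default rate 0.02, a
typical exome no-call fraction; real panels have structured per-variant
call rates that this deliberately does not model). Default F = 0.1 per
population, a realistic continental-scale divergence. Loci are
independent: no linkage disequilibrium, selection or demography, so
passing tests demonstrate correctness of the statistical machinery, not
realism of haplotype structure. One global integer seed drives everything
through deterministic child streams (`SeedSequence` spawn keys per
operation), making panels bit-identical across runs.

A Weir-style ratio-of-sums F_ST estimator
(F̂ = Σ s² / Σ (p̄(1−p̄) + s²/r), with s² the across-population sample
variance per locus) validates the generator: over 1,000 loci it recovers
configured F ∈ {0.05, 0.1, 0.2} within ±0.02.

## Problem sizes and numerical choices

The test suite runs the pipeline on scaled-down panels (7 populations of
5–30 samples, 25–60 variants, 49–199 permutations); the PERMANOVA type-I
calibration uses 500 replicates of two 20-sample groups at 50 loci with
199 permutations; Fisher/Hochberg oracle checks use 200 random
118-margin tables and random p-vectors. Full study-scale runs (2,568
samples, 999 permutations) are supported and take minutes on one core.

Tolerances: Fisher tie tolerance 1e−7 (relative); oracle agreement
asserted at 1e−9; MDS exactness at 1e−9; eigenvalue nonnegativity at
−1e−9; R² clipped to [0,1] against ~1e−16 float drift. Degenerate inputs:
empty annotation panels yield zero counts with percentages flagged
undefined; all-missing dosage vectors raise; a 2×2 table with a zero
margin has a single attainable configuration and returns p = 1;
zero-distance MDS returns an empty (all-zero) embedding with a warning.

## Known limitations

* The generator's missingness and frequency model cannot reproduce the
  real panel's per-variant call-count pattern, and the original cohort's
  data-dependent outcomes (e.g. which and how many variants survive the
  inclusion filter) are not reproducible without the cohort.
* Fixture transcriptions inherit the source's printing artefacts (the
  truncated percentages above; one row labelled NOS3 in the table but
  NOS1 in the running text — both labels are stored).
* No odds ratios/CIs, no mid-p exact tests, no PERMDISP, no multi-factor
  PERMANOVA, no non-metric MDS.
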