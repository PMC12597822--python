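# Methods

## Coordinate system and reference

Human mtDNA is a 16,569-bp circle; all coordinates are 1-based closed
intervals in rCRS numbering (m.1227 = position 1227). Trinucleotide
contexts wrap across the origin (position 1's context uses positions
16569 and 2) — mtDNA circularity makes this the only non-arbitrary choice.
The package bundles the real 37-gene rCRS coordinate table. The nucleotide
sequence itself is not bundled: `load_reference` accepts a sequence string
or FASTA, and otherwise generates a seeded synthetic sequence with
rCRS-like base composition (A 0.31, C 0.31, G 0.13, T 0.25). All
simulation studies use such a synthetic sequence, so context *abundances*
are realistic in distribution but not identical to rCRS.

Overlapping genes (e.g. MT-ATP8/MT-ATP6) are resolved deterministically to
the gene with the smaller start coordinate, ties by name; this is a
documented convention, not a biological claim, and can be overridden by
editing the gene list. The control region defaults to the wrapping
interval [16024, 576]; the blacklist to {[513, 525], [3105, 3109]}.

## Somatic retention rules

A call is retained iff tumor heteroplasmy > 0.05 (strict), matched-normal
heteroplasmy < 0.01 (strict), at least 2 alt reads on each strand, and the
position is outside the blacklist. The 5% threshold is a parameter, not a
constant: a 1% threshold is known to admit strand-artifact calls marked by
noncanonical T>G enrichment, which is why 5% is the default. Control-region
calls are retained by the filter; the control region is removed later, at
hotspot testing, preserving the stage ordering of the analysis. Indel rows
pass through the same rules with a warning since no indel-specific rule
set is defined; there is no indel recurrence statistic.

## Mutability model and recurrence test

μ_context is the fraction of all retained somatic SNVs (outside control
region and blacklist, deduplicated per sample/position/allele) whose
position carries each of the 64 reference trinucleotides; the 64 values
sum to 1. μ_pos is the μ of a position's own context, μ_gene the sum of
μ_pos over the gene's nonzero-μ positions, and the binomial success
probability is P_pos,gene = μ_pos/μ_gene. A position with x mutated tumors
out of n tumor-deduplicated mutation events in its gene is scored with the
one-sided upper tail P(X ≥ x), computed through the regularized incomplete
beta function (numerically exact at cohort scale; validated against
brute-force pmf summation to 1e-10 for all n ≤ 1000).

Counting: a (tumor, position) pair contributes at most 1 to x and at most
1 to n — recurrence means independent patients — so within a gene the x
values sum to n in position mode.

Testing family: `position` mode (default) tests every position with
nonzero context mutability inside a gene with observed mutations,
*including* positions never observed mutated (p = 1). This makes the null
p-values unconditionally valid, so the false-discovery control of the BH
step-up applies to the family as a whole; restricting the family to
observed positions would condition on X ≥ 1 and can push the rejection
rate above the nominal level. `allele` mode tests observed (position, alt)
units only, matching a per-mutant-allele reading; both are exposed because
the position and allele vocabularies describe the same procedure at
different granularity. Positions whose context never mutated are
untestable by construction and are excluded (logged if they somehow carry
observations under an externally supplied model).

Known limitation (measured on null cohorts): because μ_context is a
mutation *frequency* not normalized by how often the context occurs in the
genome, P_pos,gene overstates the landing probability at positions of
common contexts (conservative) and understates it at rare-context
positions (anti-conservative). Pooled null calibration remains
conservative at the 0.05 level (fraction of tested positions with p < 0.05
≈ 0.03), but the extreme tail (p < 1e-4) runs about twice nominal, so
occasional false discoveries adjacent to the BH threshold are expected;
the spiked-recovery study measures the realized FDR.

## Enrichment and co-occurrence statistics

Germline constraint is a pure count criterion: fewer than 2 homoplasmic
carriers among the surveyed individuals (196,554 by default). Positions
absent from a carrier table read as 0 carriers. (The allele-frequency
phrasing "< 0.00001%" that sometimes accompanies this definition is
numerically inconsistent with the count — 2/196,554 ≈ 1e-5 as a fraction,
not a percent; the count criterion is authoritative here.)

Fisher exact tests and the two-sided binomial test both use the
minimum-likelihood definition of two-sidedness (sum of outcomes no more
likely than the observed one), matching `fisher.test`/`binom.test`
defaults in the reference statistical environments; doubling-method users
will see slightly different p-values. Odds ratios are cross-product ratios
ad/bc with ∞ when bc = 0 and ad > 0, NaN when both vanish. The Wilcoxon
rank-sum comparison uses exact enumeration for groups of ≤ 25 without
ties, and the tie-corrected normal approximation otherwise.

Constraint enrichment accepts either denominator — all non-hotspot
*mutated* positions or all positions of the genes — as the comparison set;
the contingency construction is the caller's modelling choice and both are
legitimate questions.

Co-occurrence screens test, within each cancer type, every nuclear gene
mutated in ≥ 5% of that type's patients against five nested mtDNA
alteration levels (any, truncating, hotspot, any rRNA, rRNA hotspot),
using the 2×2 chi-squared without continuity correction (a flag enables
Yates). Tables with any expected cell below 5 are flagged, not suppressed;
degenerate margins are skipped. Adjustment is BH across the full result
family, with a Bonferroni switch.

## Single-cell pipeline

Heteroplasmy is alt/(alt+ref) per cell, undefined (error) at zero
coverage. QC retains cells with 1,000 ≤ features ≤ 7,000, ≤ 5%
mitochondrial expression, and strictly 25 < locus coverage < 250 (the
printed rules remove cells with *fewer than* 1,000 / *greater than* 7,000
features, so the bounds themselves survive; the coverage window is
strict).

Per-gene association uses Spearman correlation over cells with nonzero
expression of the gene, requiring strictly more than 50 such cells;
mid-ranks handle ties, p-values use the t approximation above n = 30 and
exact permutation below. Rank statistics make the raw-counts vs
log-normalized question moot (any strictly monotone transform gives the
same ρ). Coefficients are Fisher Z-transformed (atanh), with |ρ| = 1
capped at atanh(1 − 1e−12) to keep deltas finite on degenerate bins, and
exported as a ranked list (descending Z, ties broken by gene name) for
preranked enrichment tools. The covariate regression is OLS of expression
on the primary-locus heteroplasmy plus covariate-locus heteroplasmies;
constant covariates are dropped (they cannot confound, and this lets
all-zero covariates reduce exactly to the simple slope); genuinely
collinear designs raise with the offending column names.

The threshold scan splits cells at each t ∈ {0.1, …, 0.9} into lower
(h ≤ t) and upper (h > t) groups — the boundary cell goes to the lower
group by default, configurable — computes per-side Spearman/Fisher-Z for
every gene with ≥ 100 nonzero-expression cells on each side, and records
Δ = |z_upper − z_lower|. The per-bin aggregate is the median Δ over
eligible genes; the argmax bin localizes the dosage threshold. Bins with
no eligible genes are reported empty.

## Synthetic-data generators (study conditions)

All generators are pure functions of (config, seed).

**Cohort.** Each tumor acquires Poisson-distributed background SNVs (mean
1.4 per tumor, the burden observed in population-scale tumor mtDNA
sequencing), placed by sampling (position, alt) proportional to a
signature keyed on (control vs non-control region) × substitution:
pyrimidine-strand C>T and T>C dominate outside the control region and the
asymmetry is mirrored inside it. Tumor heteroplasmies are
0.05 + 0.95·Beta(1.2, 3) (the calling floor plus a right tail), normal
noise 0.01·Beta(1, 30), depth Poisson(1000), strand split Binomial(1/2).
Spiked hotspots are independent Bernoulli carriers per tumor; the default
studies spike 20 positions at per-tumor probability 0.004 (~40× the mean
per-position background rate, ~20 carriers per 5,000 tumors — comparable
to real hotspot recurrence). Spiking a blacklisted position is a
configuration error since such an allele could never be detected.

**Germline table.** Constrained positions draw 0–1 carriers, polymorphic
positions 2 + Geometric; unlisted positions are implicitly 0.

**Single cell.** Heteroplasmy is a two-component mixture: with probability
0.3 a near-zero Beta(0.6, 12), otherwise Beta(2, 2.2) — reproducing
distributions strongly skewed towards zero with an overall median ≈ 0.33
and ~28% of cells below 10%. Locus coverage is gamma-Poisson (mean 120,
shape 8), alt reads Binomial(coverage, h). Expression is gamma-Poisson
(negative-binomial, size 2) around lognormal gene means, with dropout 5%
and a 3% rate of deliberate QC violations so the filters have work to do.
Effect genes multiply their mean by a dosage link:

* `step` — full log2 fold change above θ;
* `hinge` — fold change scaling linearly with dosage above θ;
* `logistic` — smooth ramp centred at θ;
* `compensatory` — a mild log2 *increase* (default +1) accumulating below
  θ, then the decline above it.

The threshold-scan studies use the compensatory link. This is a deliberate
design decision: with a flat step both half-ranges are internally
uninformative when the split equals θ (the delta statistic *dips* at the
truth), and with a pure hinge every split below θ isolates the whole
effect in the upper side (the delta profile is a plateau, not a peak), so
neither makes the scan identifiable. A sub-threshold compensatory rise —
as reported for mitochondrial transcripts under truncating-mutation
burden — gives the lower side its own opposite-signed association, and
the delta then peaks sharply at the bins bracketing θ (36/36 pilot
replicates across θ ∈ {0.15, 0.25, 0.45}).

What the generators do **not** emulate: read-level errors and mapping
artifacts, NUMT contamination, tissue-specific mutational burdens
(tissues are exchangeable labels), indels, cell-type heterogeneity,
ambient RNA, and batch effects. Passing tests therefore demonstrate the
statistical machinery under its stated assumptions, not robustness to
those real-data complications.

## Validation studies and problem sizes

The packaged studies (test suite and `scripts/acceptance.py`) use: 200
signature-only cohorts of 5,000 tumors for null calibration (pooled
fraction of tested positions with p < 0.05, compared against 0.05 plus
3 Monte-Carlo SE); one 5,000-tumor cohort with 20 spikes for sensitivity
and empirical FDR at Q < 0.05; 10,000 cells × 200 genes (20 effect genes,
hinge, θ = 0.2, log2FC −1.5) for the ranking study; and 50 replicates of
2,000 cells × 25 genes (15 compensatory effect genes, log2FC −2) per
θ ∈ {0.15, 0.25, 0.45} for threshold localization. These sizes give
stable Monte-Carlo behaviour while keeping the full suite fast on a
single CPU.

## Numerical conventions

Binomial tails via the survival function (incomplete beta); BH step-up
with capping at 1 and original-order return; Fisher-Z capping at
atanh(1 − 1e−12); chi-squared without continuity correction by default;
exact vs asymptotic Wilcoxon switch at group size 25 (no ties); Spearman
exact-permutation switch at n = 30. Ties in ranked-list export break
lexicographically. Degenerate inputs (all-zero tables, empty groups, zero
coverage, constant vectors, out-of-range positions) raise explicit errors
or produce documented skips rather than NaNs.
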