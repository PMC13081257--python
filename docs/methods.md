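# Methods

This note documents the models, parameter choices and numerical conventions
behind `kinbench`, and the limits of what its synthetic benchmark can say.

## Scope

Everything in this package operates on synthetic data at desk scale: sites
are abstract biallelic markers, reads are single sampled alleles, and the
"tools" under evaluation are either the package's own PMR pipeline or
externally produced output tables. No empirical claim about the relative
accuracy of published tools on real ancient-DNA data is made or implied by
this repository; such claims require running the tools themselves on
full-scale sequence simulations.

## Pedigree model

Pedigrees are directed acyclic graphs in trio format (`id father mother`,
`0` for founder slots). The kinship coefficient φ is computed by the
standard recursion on a topological order: for individual *i* with parents
*f, m* and any *j* that is not a descendant of *i*,
φ(i, j) = ½(φ(f, j) + φ(m, j)), with φ(i, i) = ½(1 + F_i) and
F_i = φ(f, m). Founders are unrelated and non-inbred. The recursion is
memoised; evaluating the later individual of a pair first guarantees the
non-descendant precondition. The expected relationship coefficient is
r = 2φ.

Degrees form the ordinal grid Unrelated/3rd/2nd/1st/Self with expected r
values 0, 0.125, 0.25, 0.5, 1 and midpoint class boundaries 0.0625, 0.1875,
0.375, 0.75; a boundary value is assigned to the more-related class.
Relationship ties (e.g. double first cousins: two 3rd-degree ties compound
to an expected 2nd-degree r) are enumerated by Wright's path-counting over
most-recent common ancestors, grouping mated couples as a single tie.
Monozygotic twins are modelled as verbatim genotype copies and classified
Self.

## Genotype and observation simulation

Founder haplotype alleles are independent Bernoulli(p_s) draws from a
per-site frequency spectrum (uniform on [0.05, 0.95] by default; a U-shaped
Beta option exists). Descendants receive gametes under the Haldane
no-interference model: each chromosome's crossover count is Poisson with
mean equal to its genetic length, breakpoints are uniform, and sites are
evenly spaced in genetic distance. Defaults: 35 Morgans split over 22
chromosomes, approximating a human autosomal map.

The sequencing emulation works at the called-site level rather than the
read level: per individual and site, depth ~ Poisson(coverage); zero depth
gives a missing call; otherwise one read is chosen uniformly. The read's
source is a single contaminant individual with probability `contamination`,
else the endogenous genotype; it carries one uniformly chosen allele of its
source, flipped with probability `error` (a symmetric stand-in for residual
damage and sequencing error). Under this model
E[PMR] = (1 − r/2) · mean(2p(1−p)) for error- and contamination-free pairs,
which the calibration tests verify to Monte-Carlo precision.

## Estimation

The PMR of a pair is the mismatch fraction over jointly covered sites.
Normalisation is either by the cohort median PMR (appropriate when most
pairs are unrelated; the median convention for even counts is the mean of
the central values) or by the analytic unrelated expectation
mean(2p(1−p)). From normalised P0, r = 2(1 − P0). Native statistics of
external tools convert as: r = k1/2 + k2 (Cotterman), r = 2(1 − PWD_obs /
PWD_unrelated), r = 2φ. "Uncertain" correctKin rows and pairs absent from
correctKin output are treated as unrelated. The Queller & Goodnight
single-locus estimator in its pseudo-haploid adaptation returns 1 for
identical alleles and 1 − 1/(2p) − 1/(2(1−p)) on a mismatch; fixed sites are
excluded.

## Damage masking

Profile-driven masking takes per-position terminal misincorporation rates
(simplified two-column tables or mapDamage `misincorporation.txt`, with
C>T/C on 5' rows and G>A/G on 3' rows aggregated over chromosomes and
strands). The masking window at each end extends outward-in while the rate
is ≥ 1% (threshold configurable) and stops at the first sub-threshold
position. Within the windows, positions whose aligned reference base is
susceptible — C in the 5' window, G in the 3' window, in fragment
orientation, complemented for reverse-strand reads — become N with base
quality 0. A fixed-window variant masks the first/last k bases
unconditionally. Masking preserves read length and headers and is
idempotent; indel-free alignments only.

## Metrics

**UOC.** For a K-class confusion matrix with row totals N_r, observed-row
indicator 1∂(r), observed-class count K′, share n_rc/N_r·1∂(r), distance
|r−c|^γ (γ = 1 throughout), the index at penalty weight β is the minimum
over consistent paths (monotone chains from the top-left to the
bottom-right cell with right/down/diagonal steps) of

    1 − S_path/D + (β/K′)·P_path,
    D = K′ + (K′/K′^γ)(Σ_all share·dist)^(1/γ),

where S_path and P_path sum share and share·dist along the path. Because
per-cell costs are additive, the minimisation is solved exactly by dynamic
programming, vectorised over a 101-point β grid; β is then eliminated by
trapezoidal integration over [0, 1]. The per-β value lies in [0, 1]
analytically; a final clip guards floating-point jitter at the bounds. An
exhaustive path enumerator (central Delannoy counts 1, 3, 13, 63, 321 for
K = 1…5) serves as the test oracle.

**Accuracy/bias.** Per degree, r estimates are summarised as RMSD and mean
bias about the grid expectation, normalised by half the span between
neighbouring grid values ((r_{k+1} − r_{k−1})/2; edge classes use the
one-sided span — Unrelated 0.125, Self 0.5; Second-degree denominator
0.1875). The nRMSD 95% CI is the multiplicative interval
nRMSD·[√(1−q), √(1+q)] with q = 1.96·√2/√(N−1), the lower bound undefined
(NaN) when q > 1; the nMBE CI is ±1.96σ/√N on the normalised scale. 1.96
is the rounded two-sided 95% normal quantile.

**Aggregation.** Mean UOC across replicates carries a normal-approximation
CI; the coverage response is summarised as the trapezoidal AUC of
1 − mean UOC over the coverage grid, normalised by the coverage span so a
perfect method scores 1. One-vs-all sensitivity/specificity/balanced
accuracy/precision/F1 are reported per class, with NaN (not 0) for classes
absent from both truth and prediction.

## Reproducibility

All benchmark randomness derives from one integer seed via
`numpy.random.SeedSequence(entropy=seed, spawn_key=(condition, replicate))`,
so any configuration reproduces byte-identical report files.

## Limitations

- The observation model samples alleles at called sites; it does not model
  read length, mapping, base-quality recalibration, reference bias, or
  within-read damage position, so masking and estimation are benchmarked on
  separate synthetic substrates.
- Contamination uses a single shared contaminant for all samples, the
  worst case for pairwise methods (it biases pairs toward apparent
  relatedness); sample-specific contaminants are not modelled.
- Site frequencies are known exactly to the reference-expectation
  normaliser; frequency misspecification is out of scope.
- The kinship recursion assumes founders are unrelated and non-inbred, and
  pedigree sex is ignored (no X-chromosome model).
- External tools are evaluated only through their output tables; this
  package does not run them.
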