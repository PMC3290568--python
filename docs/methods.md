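# Methods

This note documents the models implemented in `standscan`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Coordinates and data model

Haplotypes are phased 0/1 matrices over biallelic SNPs with 0 the
ancestral allele, 1-based strictly increasing chromosomal positions and
half-open `[start, end)` regions. Sites that cannot be polarized (the
ancestral base matches neither observed allele) or that contain missing
calls are dropped on load — never imputed — and counted in a load
report. Monomorphic sites are retained on load; each statistic excludes
them as its definition requires. Per-bp statistics are normalized by the
*surveyed* length L (the number of base pairs actually sequenced), which
must be supplied explicitly; the coordinate span is never used as a
stand-in. Tabular outputs print π and θ_W scaled by 10⁴ per bp, the
convention of resequencing-survey tables; internal values are unscaled.

## Summary statistics

π uses the unbiased frequency form Σ 2p(1−p)·n/(n−1), which equals exact
pairwise enumeration (tested to 1e−12). θ_W = S/(a₁L). Tajima's D uses
the standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants; with S = 0 the
statistic is undefined and reported as NaN, never 0. The choice of the
unbiased π estimator reproduces the published per-region D values from
their printed inputs to the printed precision, which is how the
estimator convention was fixed.

## Coalescent simulator

A backward-in-time ancestral-recombination-graph simulator in the
Hudson tradition, written against the following scaling: time in units
of 4N₀ generations, where N₀ is the demographic model's reference
(equilibrium/ancestral) size; pairwise coalescence rate 2 per pair;
per-lineage crossover rate ρ·span, gene-conversion initiation rate
f·ρ·(1+λ) with tract lengths exponential of mean λ = tract_mean/L (the
continuous analogue of geometric tracts; the (1+λ) term accounts for
tracts initiating left of the locus and overlapping it); mutation rate
θ per unit ancestral material. Ancestral material is tracked as
segments carrying descendant-sample bitmasks; segments reaching their
marginal MRCA leave the state. Mutation opportunity (branch length ×
segment length) is accumulated exactly per lineage segment, so
mutations can be dropped either as Poisson(θ × total opportunity) or as
exactly S draws proportional to opportunity ("fixed-S"), matching the
`-s` conditioning of classical simulators. Infinite-sites positions are
uniform on the locus and mapped to integer bp (collisions bumped to the
next free coordinate).

Demographic encodings (times in generations before present):
instantaneous expansion (size N₁ until t, N₀ before); exponential
two-fold growth from N₀ at t to 2N₀ now; piecewise bottleneck of
intensity b during [t₁, t₀]; symmetric n-island structure with scaled
per-lineage migration rate m/2 in scaled units; a coarse two-epoch "best_fit" preset
(N₀ = 12,500 ancestral, 24,000 recent from 5,000 generations) standing
in for a fully calibrated history whose complete parameterization is
not restated here. Exponential-growth epochs use the closed-form
inverse of the inhomogeneous coalescence hazard; all other epochs are
piecewise constant with resampling at boundaries.

Two properties anchor the engine: E[S] = θ·a₁ and E[π] = θ under
constant size (checked within 3 SE), Var(S) = a₁θ + a₂θ² without
recombination, a 1/i frequency spectrum, decreasing Var(π) with ρ, and
a two-sample KS agreement of the S distribution with an independent
established coalescent simulator at matched parameters (gene conversion
included).

**Fixed-S versus fixed-θ nulls.** The package supports both. The
published 97.5th percentiles this package reproduces are attainable only
under fixed-S conditioning (π's null spread under fixed-θ is ~45%
wider); the acceptance computation therefore conditions each replicate
on the observed S = 62, with θ and ρ at their estimated per-bp values.
Replicates with S = 0 (possible only in θ mode) are excluded from the
Tajima's D null and counted.

Reproducibility: replicate i draws its generator from a SHA-256-derived
child seed of (seed, i), so null distributions are bitwise reproducible
and insensitive to execution order.

## Linkage disequilibrium

D = p₁₁ − p₁q₁; |D′| normalizes by the frequency-bound maximum; r² by
the product of allele variances. |D′| is reported as an absolute value
(the plotting convention); signed D is available. The LD-matrix MAF
filter defaults to 0.05 (the common Haploview-like choice; configurable).
Complete-LD grouping takes the transitive closure (union-find) of pairs
with |D′| ≥ 1 and r² ≥ 0.9 by default — the criterion used in the
analyses this package supports to treat co-segregating functional sites
as one variant. Confidence-interval-based haplotype-block calling is
deliberately out of scope.

## EHH and iHS

EHH at a site j for an allele class is Σ_g C(c_g,2)/C(c,2) over groups
of carriers identical from the core through j; it is 1 at the core and
non-increasing outward. iHH integrates the curve by trapezoid per side
until EHH first crosses the truncation level (default 0.05), with
linear interpolation of the crossing; curves that hit the data boundary
before truncating are edge-flagged and excluded from standardization by
default. Distances are physical bp (a genetic map can be supplied);
unstandardized iHS is ln(iHH_ancestral/iHH_derived), standardized
within 20 equal-width derived-allele-frequency bins, with |iHS| > 2 as
the significance threshold (the outer ~5% of a standard normal). The
MAF floor is 0.05. For scoring a candidate site, a
`StandardizationReference` built from an independent (neutral or
genome-wide) score set avoids contaminating bin moments with sites
linked to the signal under test; this mirrors genome-wide practice,
where the standardization set is overwhelmingly neutral. The EHH walk
stops one point after falling below the truncation level, which turns
the naive O(sites²) scan into a local one; the stored curve is exactly
what the integral consumes.

## Allele age from haplotype sharing

For each carrier ("case") chromosome and each side of the core, the
genetic distance to the first departure from the shared ancestral
haplotype is modeled as exponential with rate G (the age in
generations) per Morgan, plus a mutation hazard μ per marker scanned
(default 2.5×10⁻⁸ per marker per generation). The censored-exponential
MLE is Ĝ = U / Σ(dᵢ + μkᵢ) over all case-side observations (censored
sides contribute exposure but no event); τ = 1/Ĝ; years = generations ×
generation time (default 25 y). When every observation is censored the
age is reported as unresolved rather than 0 or ∞.

Two refinements matter in practice and are on by default:

1. *Sequential-majority consensus.* The ancestral haplotype is
   reconstructed marker by marker by majority vote among carriers still
   identical to the consensus so far. A global majority vote drifts to
   the recombined background once most copies have broken, generating
   false breaks for young alleles; the sequential vote follows the
   surviving intact copies. A known ancestral haplotype can be supplied
   instead.
2. *Coincidental-sharing correction.* A recombined case keeps matching
   the consensus by chance (allele-frequency matching plus background
   LD), pushing observed breaks beyond the true recombination point and
   biasing ages downward — increasingly so for old alleles. When
   control (non-carrier) haplotypes are supplied, the mean distance
   over which controls match the consensus estimates that overshoot,
   and U times it is subtracted from the exposure (capped at half the
   exposure). This is the case-control structure the
   haplotype-sharing-decay approach assumes.

A nonparametric bootstrap over carriers gives a percentile CI. This
estimator is a deliberate simplification of full haplotype-sharing
likelihood machinery; its validation is parameter recovery on synthetic
sweeps (median relative error ≤ 30% across ages 100, 400 and 1,600
generations under the recovery scenario below), not bit-equivalence to
any particular fine-mapping package. Mutation-rate calibration from
interspecies divergence uses μ = Dxy/(2·T_split/T_gen): divergence
accumulates along both lineages since the split.

## Environmental correlation

Pathogen richness is the per-country count of pathogen species present,
restricted to selected classes (virus/bacteria/protozoa). Kendall's
τ-b is used throughout because country-level richness induces heavy
ties when several populations share a country. P-values: exact null
enumeration via the inversion-count (Mahonian) recurrence for tie-free
data with n ≤ 10; otherwise a normal approximation with tie-corrected
variance and continuity correction; a permutation test is available as
the assumption-free fallback and is the basis of the type-I-error
check (≤ 0.06 at nominal 0.05 with n = 21 tied observations). Multiple
populations per country are kept as separate observations with tied
richness by default; collapsing to country means is an option.

## Counting dN/dS

NG86-style: per codon position, the synonymous fraction is the share of
single-base changes to sense codons preserving the amino acid, with
changes to stops excluded from the denominator, so N + S sites sum to
3 per codon. Differences at multi-hit codons are averaged over all
minimal pathways that avoid stop codons (unweighted; pathways through
stops discarded). Jukes–Cantor correction d = −¾ln(1 − 4p/3) is applied
to both proportions; p ≥ ¾ or dS = 0 yield flagged undefined values.
Codons containing a stop in any compared sequence are excluded from the
counts and reported separately — they carry a pseudogenization signal,
not a rate. Lineage assignment is strict-consensus parsimony: a change
is assigned to the focal branch only when all (≥2) outgroups agree and
the focal codon differs. ω is classified against 1 with a configurable
neutrality band. Maximum-likelihood codon models are out of scope;
the counting estimator is not expected to reproduce their estimates.

## Synthetic-data generators

All generators are deterministic under a fixed seed and emit a truth
record; recovery tests read truth only through it.

*Sweeps* are injected by copying: a template haplotype drawn from
outside the carrier set donates the ancestral haplotype; each carrier
receives a copy truncated on each side at an Exponential(age) genetic
distance (its own background splices back beyond the break) and
overlaid with per-marker mutation noise μ × age. This reproduces
exactly the haplotype-sharing decay and extended-homozygosity structure
the DHS and iHS estimators detect, with controllable truth. Keeping
the template donor out of the carrier set matters: a carrier whose
spliced background *is* the template would never exhibit a scar and
would enter the age likelihood as an unbreakable censored observation.
The `core_window` option confines the core to a central fraction of
the region so the sharing signal is not truncated at the boundaries.
What this generator does **not** emulate: the frequency trajectory of a
real sweep, hitchhiking-driven frequency spectra in the flanks, or a
heterogeneous recombination map. Passing recovery tests therefore shows
the estimators work when their decay model holds, not that real sweeps
of that age would be dated equally well.

*Environmental effects* use a Gaussian copula: country richness from a
random presence/absence matrix, normal scores from average ranks (tied
countries share a score), population frequencies Φ(ρz + √(1−ρ²)ε) with
ρ = sin(πτ*/2) so the planted Kendall strength is approximately τ*,
plus optional clipping noise. It does not model population structure or
spatial autocorrelation, which in real data inflate apparent
environment–frequency correlations.

*Codon alignments* evolve each codon independently along a 3-taxon star
tree under a continuous-time walk in which synonymous single-base
changes are accepted at relative rate 1 and nonsynonymous at rate ω,
with stops forbidden. No codon-frequency or transition/transversion
structure is modeled.

## Problem sizes used in the test suite

Stochastic checks are scaled to keep the suite fast while leaving
Monte-Carlo error well inside each tolerance: simulator calibration at
5,000 replicates of the survey-sized locus (n = 40, L = 9,209 bp);
published-percentile checks at 4,000 fixed-S replicates (the acceptance
script uses 10,000); iHS calibration on one 600-kb neutral region
(~1,000 scored sites) and power on 15 planted sweeps of age 1,200
generations at frequencies 0.4–0.8 in 300-kb regions; DHS recovery at
25 replicates per age on 300-kb regions with a 10⁻⁷ M/bp map (sharing
tracts of ~6–100 kb, well above marker spacing and below the region
size); ω recovery at 25 alignments of 300 codons per ω; Kendall type-I
error at 2,000 permutation-null replicates of n = 21. The SFS check
uses replicate-level standard errors per frequency class (within a
replicate, site counts are correlated through the shared genealogy, so
a Poisson chi-square would be miscalibrated).

## Known limitations

- The recent-expansion null (instantaneous N₀ = 10⁴ → N₁ = 10⁷ at 1,000
  generations) yields 97.5th percentiles of π×10⁴ ≈ 20 and D ≈ 1.0
  under both mutation modes and across expansion magnitudes 10⁵–10⁷;
  under fixed-S conditioning the π and D percentiles are moreover
  deterministically linked. Published values for this model that do not
  satisfy that link cannot be reproduced from the printed parameters,
  and the corresponding checks are expected to fail; the constant-size
  null reproduces within ~3%.
- The simulator is single-locus, neutral, and has no intra-locus rate
  heterogeneity; selection enters only through the synthetic sweep
  generator.
- The DHS estimator assumes a star genealogy of carriers and a known
  (or reconstructible) ancestral haplotype; for very young alleles with
  few breaks the estimate rests on few events and the bootstrap CI is
  wide.
- Kendall's exact p-value is only available for tie-free data (n ≤ 10);
  tied small samples fall back to the normal approximation or the
  permutation test.
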