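# Methods

`newtflow` infers the divergence history of two hybridizing newt species
(*Lissotriton vulgaris*, Lv, population 1; *L. montandoni*, Lm, population 2)
from the unfolded joint site frequency spectrum (SFS) of transcriptome SNPs,
including genomically heterogeneous gene flow modeled as a two-class mixture
of expected spectra.  This note records the models, the numerics, and the
design choices where the design was genuinely open.

## Model family

All sixteen models share a skeleton: an ancestral population at equilibrium
splits instantaneously into Lv and Lm, which then pass through one or two
epochs.  Scenario classes: strict isolation (SI, SIG), ancient migration
(AM, AMHET: gene flow first, then isolation), secondary contact (SC, SCHET,
SCG, SCGHET, SCIG, SCIGHET, SCMG, SCMGHET: isolation first, then gene flow),
and isolation-with-migration (IM, IMHET, IMG, IMGHET).  `*G*` variants let
population sizes change exponentially (within an epoch
`N(t) = N_start * exp(t/T * ln(N_end/N_start))`, forward time); `*HET`
variants carry two migration-rate pairs and a mixture weight `P`, the genome
fraction in class 1.

Units follow the diffusion convention: sizes `nu` relative to the ancestral
diploid size `N_A`; times in `2 N_A` generations; migration
`M_ij = 2 N_A m_ij`, where `m_ij` is the per-generation fraction of
population *i* that are new migrants *from* population *j* (so `m12` is
gene flow into Lv).  Models with a founding fraction use `s` for the
fraction of the ancestral population founding Lm, i.e. start sizes
`(1-s, s)`; the source study uses "population 1/2" inconsistently between
its text and its parameter table, and the table's orientation (s founding
Lm, declining under the fitted values) is adopted as ground truth.

The exact per-model parameter lists (see `newtflow.models`) are a
**reconstruction**: the study describes its sixteen models in prose but the
full supplementary parameter table was not available.  Counts are
cross-checked against the parameters its main table reports for SCGHET
(12 free parameters plus theta).  Two prose ambiguities were resolved as
follows: SIG starts the descendants at relative size 1 (not at free start
sizes), and SCMG starts them directly at the isolation-epoch sizes (it has
no `s`).

## Expected spectra: a moment system on the sample SFS

The engine (`newtflow.engine`) evolves the expected sample spectrum
`Phi[i, j]` (derived-allele count `i` of `n1` in Lv, `j` of `n2` in Lm)
directly, as in moment-closure approaches to the two-population diffusion.
Integrating the diffusion generator against Bernstein sampling polynomials
`b_{n,i}(x) = C(n,i) x^i (1-x)^{n-i}` gives, per unit `theta = 4 N_A mu L`:

* **Drift** (exact, tridiagonal in each index):
  `dPhi_i/dt = 1/(2 nu) [ (i-1)(n-i+1) Phi_{i-1} - 2i(n-i) Phi_i
  + (i+1)(n-i-1) Phi_{i+1} ]`.
  At `nu = 1` with the mutation source this leaves `Phi_i = theta/i`
  stationary, exactly.
* **Mutation** (exact): new singletons enter cell `(1,0)` at rate `n1/2`
  and `(0,1)` at rate `n2/2` per unit time per unit theta.
* **Migration** (the generator `M (x_b - x_a) d/dx_a` is exact; closure is
  the one approximation): the `x_b` factor raises the source population's
  sampling degree by one, so the term references the spectrum at sample
  size `n_b + 1`.  That spectrum is estimated from size `n_b` by an
  **atom-aware, projection-consistent quadratic closure**:
  - interior entries: quadratic interpolation of the underlying density,
    fitted only through interior entries (the extreme entries contain
    boundary point masses -- classes lost or fixed -- which would corrupt
    the fit);
  - extreme entries: the corresponding extreme source entry (the atom)
    plus a quadratic correction for the change of sampling kernel;
  - finally the estimate is corrected to satisfy hypergeometric
    subsampling consistency exactly, which holds for any underlying
    measure and removes the closure-error component visible to the
    projection.

The initial condition is the ancestral equilibrium `theta/k` at pooled size
`n1 + n2`, redistributed hypergeometrically over the two samples at the
split, so ancestral standing variation is carried through.  Epochs with
constant coefficients are advanced by a single matrix exponential (the
constant source handled by one augmented coordinate, i.e. exactly);
exponential-size epochs use an exponential-midpoint rule with the exact
per-segment average of `1/nu(t)` (default 24 segments per epoch; results
change by <0.6% from 24 to 96 at the sizes used here).  Corner cells
(0,0) and (n1, n2) accumulate absorbed mass and are masked on output.

Heterogeneous models return `P * Phi(rates_1) + (1-P) * Phi(rates_2)`,
all other parameters shared.

**Validation.** The engine shares no code with the Monte Carlo oracle
(msprime branch-mode allele-frequency spectra averaged over independent
genealogies, divided by `4 N_A`).  At sample sizes (8, 10), SI / SC /
SCGHET spectra agree with the oracle cellwise within 3 Monte Carlo SE plus
a 1% engine tolerance (tests and `scripts/acceptance.py`); standardized
residual peaks move with the oracle seed, i.e. no detectable systematic
error at that resolution.  Closure error grows toward very small sample
sizes; below `n = 4` in either population the closure falls back to a
plain quadratic plus projection consistency.

## Composite likelihood, fitting, model choice

Each unmasked cell of the observed spectrum is treated as an independent
Poisson count with mean `theta * Phi_cell`.  `theta` has the closed-form
profile maximizer `sum(data)/sum(Phi)`.  Fits run L-BFGS-B in
log-parameter space (bounds: sizes 1e-4..100, times up to 10, migration up
to 50 with a 1e-6 floor standing in for zero, `s` and `P` in
(1e-3, 0.999)) from `n_starts` initializations: the supplied or default
start, then multiplicative log-uniform perturbations up to 2-fold
(default 50 starts; the analysis scripts use fewer since their data are
small).  Heterogeneous fits are reported with class 1 relabeled as the
lower-total-migration class (the mixture is invariant under class swap
with `P -> 1-P`).

BIC is `-2 loglik + k ln(n_obs)` with `k` the free demographic parameters
plus one for theta and `n_obs` the SNP count (sum of unmasked cells) --
the study does not define its `n_obs`; SNP count is the default and the
argument is exposed.

**Godambe-adjusted LRT.**  Composite-likelihood ratio statistics
`D = 2 (ll_full - ll_nested)` are rescaled by first-moment matching:
`D_adj = D * df / tr(H^{-1} J)` over the constrained directions at the
null optimum, compared to chi-square with `df` degrees of freedom
(default: the number of constrained parameters; the study used df = 2 for
its heterogeneity test).  `H` is the expected (Fisher) information --
curvature with the data replaced by the fitted expectation -- and `J` the
*centered* covariance of finite-difference scores (relative step 1%)
across bootstrap spectra; centering matters because the constrained-
direction score has a nonzero mean at the null optimum.  Null calibration
on 200 scaled-down replicates (IM at (6,6), 40 loci, fixed-vs-free
migration, 32 bootstrap spectra each) gives approximately uniform p-values
(KS test); the adjustment is mildly anticonservative (about 8-9% of null
p-values below 0.05) because `df/tr` is a convex function of the noisy
trace at feasible bootstrap counts.  This is a known property of
moment-matched adjustments, not tuned away here.

**Bootstraps.**  Conventional bootstrap resamples loci with replacement
(default B = 120, matching the study), rebuilds the spectrum, refits from
the full-data optimum, and reports mean +/- 1.96 SD intervals; failed
replicates are excluded and counted.  Parametric goodness of fit scores
the data and B = 100 datasets simulated under the fitted model by
composite log-likelihood and Pearson's chi-square over unmasked cells
(theta re-profiled per dataset); by default replicates are Poisson draws
from the fitted expectation, and a coalescent simulator callback can be
substituted (the study used ms with per-locus recombination rates, which
are not reproducible from its text; `SimulationConfig.rho` exposes the
per-locus rate, default 0).

## Synthetic data

`newtflow.simulate` wraps msprime: independent transcript-like loci
(free recombination between, none within by default), the registry
demography with explicit `N_A`, diploid individuals paired randomly within
populations, locality labels as bookkeeping only (species are panmictic in
the models).  Defaults follow the study design: 6+6 in-group individuals
(4 Lv / 5 Lm localities, so one-per-locality selection yields the 8 x 10
spectrum), one outgroup individual, mutation rate 6.3e-9, ~10^3 loci of a
few hundred bp.  Mutations are placed under infinite sites with multi-hit
placements rejected (at the default per-site theta ~0.01 the discarded
fraction is negligible).  The outgroup carries the ancestral allele plus
private divergence (default 5% per site, configurable; 0.058 matches the
synonymous calibration).  Observation noise is optional: negative-binomial
read depth, genotype quality `GQ = min(99, 2 * depth)`, site quality
`min(228, 3 * mean depth)`, plus a missingness rate; truth genotypes are
retained for tests.

What the generator does **not** emulate: sequencing reads and genotype-
calling errors (genotypes are exact unless degraded), assembly artifacts
(the paralog filter is exercised by chance heterozygote configurations,
not by real paralogy), intra-locus recombination by default, selection,
and within-species population structure.  Consequently, passing tests
validate the *inference machinery* under the model's own assumptions --
they cannot certify robustness to structure, linked selection, or calling
error in real data.  One visible interaction: with no intra-locus
recombination, locus-level SNP density is highly dispersed and the
>60 SNP/kb filter removes a substantial minority of simulated loci
(~28% at the default theta); this mirrors how the filter truncates the
upper diversity tail in any dataset.

## Dataset construction

The on-disk interface is an *all-sites* VCF 4.2 (GT:DP:GQ, INFO/AA for the
outgroup allele, one record per position so callable invariant sites and
the effective length L need no side channel), a locus annotation table
(0-based half-open ORF intervals, mitochondrial flag), and a sample sheet.
Filters implement the study's rules with these resolutions of unstated
details: SNP density uses the callable locus length (positions with at
least one known in-group genotype); ">60 SNP/kb" is strictly greater; the
paralog rule generalizes "all six individuals heterozygous" to "all
genotyped individuals of a species heterozygous, with at least six
genotyped", preserving the <0.05 Hardy-Weinberg probability bound
(0.5^6 ~ 0.016); the invariant-flank criterion is checked across *all*
selected individuals plus the outgroup (the stricter reading); codons are
"known" only if all three positions are known, partial codons at ORF ends
are ignored; one-per-locality selection is deterministic (lexicographic
smallest individual id) with a seedable random override, since the study
does not state its rule.  Site classification: a variant site is
synonymous iff every observed in-group allele yields the same amino acid
in the annotated frame (reference codon context; sites whose codon has a
second variant position are ambiguous and classified "other"); an
invariant site is synonymous iff fourfold degenerate; sites outside the
ORF are noncoding.  Effective length L counts callable sites of the
selected categories, variant plus invariant.

## Summary statistics

Per-locus pi, Watterson's theta, Tajima's D (per species), F_ST
(`1 - pi_S/pi_T`, `pi_S` the mean within-species diversity, `pi_T` the
*pooled-sample* diversity -- the alternative within+between average is a
known ambiguity of the source's calculator and pooled was chosen),
`d_XY`, and `d_A = d_XY - pi_S`, all missing-data-aware: per-site
computations use the genotyped chromosomes at that site, and a site enters
the per-locus denominator when each species has >= 2 genotyped chromosomes
there.  Watterson's theta sums `1/a1(n_site)` over segregating sites;
Tajima's D uses the standard variance constants at the median per-site
sample size.  All statistics are pairwise-difference based and therefore
valid on unphased consensus genotypes.  Dataset summaries report per-locus
mean and SD (denominator n-1; a single locus reports SD 0), skipping loci
where a statistic is undefined (e.g. F_ST with `pi_T = 0`).  Note the
pairwise F_ST estimator has O(1/n) finite-sample bias, so equal allele
frequencies give slightly negative values at small n.

## Unit conversion

`mu = d / (2 * split_years / gen_years)` from outgroup divergence
(0.058 synonymous / 0.036 noncoding, 18.4 MY split, 4-year generations:
6.3e-9 and 3.9e-9); `N_A = theta / (4 mu L)`; sizes `nu * N_A`; times
`tau * 2 N_A * gen_years`; migration `m = M/(2 N_A)`; effective migrants
`m * Ne(present, recipient)` in individuals per generation -- `m * Ne`,
not `m * 2 Ne`, is the definition that reproduces all eight printed
effective-migration entries, and the recipient size is the present-day
one (verified against every printed row).  Recomputing `N_A` from the
printed theta, mu and L gives ~3.62e5 against a printed 3.79e5 (outside
the printed interval); the source's exact rounding is not recoverable and
the discrepancy is left as is.

## Problem sizes used in validation

The packaged checks run at desk scale by design: oracle cross-validation
at (8,10) with 6e4 genealogies per model; SCGHET recovery from a Poisson
spectrum at theta = 8757 (the published DemSyn value) with 2 starts from
the generating values; LRT calibration on 200 replicates of a 40-locus IM
dataset; filter fidelity on 40 simulated loci.  The study-scale analysis
(thousands of loci, 50 starts, B = 120) is what the defaults encode.

## Known limitations

* Closure error in the migration operator is the engine's accuracy floor
  (~1% at (8,10), larger at very small n or extreme migration).
* The LRT adjustment is first-moment matching only; its mild
  anticonservatism at small bootstrap counts is documented above.
* `P` is unidentifiable when the two migration classes coincide, the
  usual boundary caveat for mixture LRTs; the packaged heterogeneity test
  follows the study in using df = 2 regardless.
* Theta and population sizes trade off along a likelihood ridge at small
  SNP counts; bootstrap intervals reflect this (wide, correlated).
* Real-data robustness (structure, selection, calling error) is out of
  scope of the generator by construction, as noted above.
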