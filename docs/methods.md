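# Methods

This note documents the models and estimators `specstruct` implements, the
choices made where the design was genuinely open, and what the synthetic
studies do and do not establish.

## Time conventions

All modules use forward time t ∈ [0, T], t = 0 at the crown and t = T at
the present.  The pulled-rate identities are native to age τ = T − t:

- pulled speciation rate λ_p(τ) = λ(τ)(1 − E(τ)), with E the probability
  that a lineage alive at age τ leaves no sampled descendant;
- pulled diversification rate r_p(τ) = λ − μ + (dλ/dτ)/λ
  = λ_p + (dλ_p/dτ)/λ_p.

The second identity follows from the backward Kolmogorov equation for E:
d ln λ_p/dτ = λ′(τ)/λ − (1 − E)(μ − λE)/(1 − E) = [λ − μ + λ′(τ)/λ] − λ_p.
Note the derivative must be in *age*: the forward-time combination
λ − μ + λ′(t)/λ is **not** constant across a congruence class.  In code the
derivative terms therefore carry a minus sign on the forward-time grid.

## Pulled-rate estimation

`pulled_speciation_rate` fits a cubic least-squares spline to
(t_k, ln M(t_k)) at the LTT jump times (interior knots at quantiles;
`smoothing_df` = number of spline coefficients) and evaluates its derivative
on a uniform grid; negative values are clipped to zero and counted.  The
default `smoothing_df = 6` was chosen by the constant-rate oracle: on 100
simulated birth–death trees (λ = 0.3, μ = 0.1, ρ = 1, ≥ 200 tips) the mean
absolute relative error against the closed form λ(1 − E) over the middle
80% of the grid is ≈ 13% at df 6 and grows with df.  Near the root the LTT
carries only a handful of lineages, so the first ~10% of the grid is
noise-dominated; estimates there should not be over-read.

## The congruence map

Given a reference r_p and a proposed extinction trajectory μ*(t), the
congruent speciation rate solves dλ*/dτ = λ*(r_p + μ* − λ*) with the shared
present-day anchor λ*(T) = λ(T) (all class members at fixed ρ agree at the
present, since λ_p(0) = ρλ(T)).  The equation is Riccati; in y = 1/λ* it is
linear, and the rootward integrating-factor solution

    y(t) = e^{C(t) − C(T)} y(T) + ∫_t^T e^{C(t) − C(s)} ds,   C′ = r_p + μ*

is a sum of positive terms and therefore unconditionally stable (a direct
nonlinear backward solver is exponentially unstable and fails on valid
members).  C is accumulated by trapezoid (exact for the piecewise-linear
integrand) and the remaining integral by per-segment Simpson on a 10×
refined grid; identity members are recovered to ~1e-13.

**Failure and certification.**  A replicate is marked failed (never raised)
when λ* leaves (0, 1.0] — e.g. a proposal like μ* ≡ 1 against a small
present-day λ — when it moves faster than the analysis grid can represent
(per-slice |Δ ln λ*| > 0.35), or when the a posteriori congruence residual
‖r_p(λ*, μ*) − r_p‖∞, recomputed with the module's own finite-difference
operator, exceeds `rp_tol` (default 1e-3).  The residual check skips a
±2-slice window around genuine discontinuities of the proposal, where the
slice-level derivative is undefined rather than wrong.  Certification is
standard a posteriori error control: heavy-tailed (horseshoe) trajectory
draws occasionally contain features a 100-slice grid cannot resolve, and
emitting such members would silently violate the class invariant.  Failed
counts are always reported and failed replicates never enter trend
summaries.

Finite differences are taken in log space (d ln λ/dt), which is exact
wherever λ changes exponentially — precisely the regime where λ* is small
and a plain difference ratio loses accuracy — with second-order one-sided
stencils at the grid ends.

## The 11 trajectory families

The source framework names the families only loosely, so the id mapping is
a package choice: 1 GMRF (log random walk) extinction, 2 linear twofold
increase, 3 linear twofold decrease, 4 exponential increase, 5 exponential
decrease, 6 HSMRF (horseshoe-scaled walk) extinction, 7 GMRF speciation,
8 linear increase, 9 linear decrease, 10 exponential decrease (speciation),
11 episodic extinction: one uniform shift time, a twofold level change of
random direction, and iid lognormal slice noise (sd 0.05 log units).
Extinction is clipped to [0, 1.0]; speciation proposals are capped at 0.5.

MRF walks are drawn on 12 knots spanning the grid and interpolated with a
C² cubic spline in log space: temporally autocorrelated, but smooth enough
that slice-level finite differences keep their nominal accuracy (a walk
jagged at the grid scale would put an O(h) kink error into every
derivative).  The increment scale σ is calibrated by internal simulation so
the max/min fold change of the interpolated walk stays ≤ 2 in ~97.5% of
draws — the "twofold change" convention with margin.  Model 11's slice
noise has an irreducible finite-difference floor (|second difference|/4 ≈
4e-3 at these settings), so the pipeline certifies episodic members at
rp_tol = 1e-2; the smooth and MRF families keep 1e-3.

## Trend classification

`classify_trends` compares λ at adjacent slices: increasing if
Δ > threshold, decreasing if Δ < −threshold, else flat (default threshold
0.02 events/lineage/My per slice, the convention of the analysis this
package supports; a `mode="derivative"` switch divides by the slice width,
and `window_slices` widens the comparison window).  Per-slice category
frequencies are computed over non-failed replicates; the modal category
breaks ties as flat.  Worth stating plainly: a rate declining linearly from
0.3 to 0.1 over 23 My changes by 0.002 per slice on a 100-slice grid — an
order of magnitude below a 0.02 per-slice threshold — so shallow monotone
declines classify as "flat" at that threshold regardless of estimator
quality; detecting them needs a smaller threshold, a wider window, or a
decline concentrated in a short interval (as in a Pleistocene downturn).

## Reference fit from data

`fit_reference` turns an estimated λ_p into a constant-extinction reference:
r_p from the λ_p identity (with λ_p floored at 1% of its maximum so
zero-clipped stretches cannot inject unbounded spikes), the present-day
anchor λ(T) = λ_p(T)/ρ, and a least-squares fit of a smooth log-speciation
curve (cubic spline through 6 knots, Nelder–Mead) so the implied r_p matches
the data.  A pointwise solve is deliberately avoided: recovering λ(t) from
noisy pulled rates rootward is exponentially ill-conditioned, which is the
congruence-class unidentifiability showing up as numerics.

## Synthetic data

**Trees** are simulated by forward Gillespie with thinning from two crown
lineages under arbitrary λ(t), μ(t); extinct lineages are pruned, tips are
sampled with probability ρ, and the crown tree of sampled tips is returned,
conditioned by rejection on a minimum tip count (and optionally on the
crown sitting at the origin, so the tree has exactly the nominal depth).
The declining preset — λ linear 0.3 → 0.1 over T = 23, μ = 0.05, ρ = 0.93 —
yields trees of ~50–120 tips.

**Spatial genotypes.**  Per site, an ancestral frequency p0 ~ U(0.1, 0.9)
and two-level individual deviations q_i = p0 ± s(p0)/2 with
s(p0) = 2·0.95·min(p0, 1 − p0); the sign comes from thresholding a spatial
Gaussian field at its median, so the sign correlation is exactly
(2/π)·arcsin(R) and the latent correlation R(d) can be solved in closed
form.  With ν = E[s²]/2 and κ₁ = E[p0(1 − p0)], the expected Hudson
numerator and denominator give

    E[Fst/(1 − Fst)] = ν(1 − ρ_sign(d)) / (2κ₁ − ν),

*linear* in the sign correlation — so setting
ρ_sign(d) = 1 − (2κ₁ − ν)(c₀ + β ln d)/ν calibrates the IBD slope exactly
in expectation (the Hudson numerator and denominator are unbiased in the
binomial genotype sampling; the only residual bias is the O(1/n_sites)
Jensen term of the ratio and linearization, measured below 1% of β at 5000
sites).  A smooth-link Gaussian process was rejected because at
individual-level Fst ≈ 0.1–0.3 the required latent variance pushes
frequencies against [0, 1], and any clipping or squashing biases the slope
by more than the recovery tolerance.  `noise_sd` adds non-spatial latent
noise (raises the intercept, leaves the slope calibration intact).
Missingness is completely at random.  Coordinates are decimal degrees on a
~200-km patch (exercising the haversine path, Earth radius 6371.0088 km).
An msprime stepping-stone generator is included as an independent
coalescent cross-check of the IBD estimators, not as the primary generator.

**mtDNA** alignments come from a UPGMA tree of pairwise coalescence times
t(d) = t₀(1 + 0.5 ln(1 + d_km)) with Jukes–Cantor mutation; for two
individuals the expected p-distance is the JC closed form
(3/4)(1 − e^{−(4/3)·2tμ}), used as the test oracle.

**Worlds.**  A declining-preset tree; 24 species sampled with 4–16
individuals and 2000 SNPs each (the study design this emulates had 33
species with 3–26 individuals); per-species β_IBD spread over [0.01, 0.10]
— in a coupled world by DR rank, in an uncoupled world randomly permuted.
The ranges are chosen so β̂ estimation noise (SE ≈ 0.005–0.01) is small
against the between-species spread, giving a sharp positive control while
the uncoupled arm stays at nominal 5% significance.

What passing these controls shows: the estimators recover the structure the
generator encodes at realistic sample sizes.  What they do not show:
robustness to features the generator omits — linkage disequilibrium,
SNP ascertainment, uneven spatial sampling, within-species admixture or
delimitation error, non-equilibrium demography, and tree-estimation error
(the tree is taken as known).

## Population-genetic estimators

- **Fst** between individuals: Hudson-type ratio of sums with each diploid
  as a two-allele sample; per co-typed site, num = (p1 − p2)² −
  p1(1 − p1) − p2(1 − p2), den = p1(1 − p2) + p2(1 − p1), summed over sites
  with den > 0.  A pair of identical fixed genotypes (all den = 0) is
  Fst = 0.  Pairs under the co-typed floor (default 50 sites) are NaN and
  flagged.  Entries ≥ 0.999 are capped before linearization and counted.
- **π**: per site with m ≥ 2 typed allele copies and alt count a,
  2(a/m)(1 − a/m)·m/(m − 1), averaged over variant sites (VCFs carry no
  invariant sites; supply your own denominator to rescale if needed).
- **Distances**: allele-sharing genetic distance Σ|a − b|/(2·co-typed) and
  per-site RMS Euclidean dosage distance; mtDNA p-distance over positions
  where both sequences are A/C/G/T.
- **β_IBD**: OLS of the chosen pairwise metric on ln(km) over unordered
  pairs; zero-distance pairs are dropped and counted.  Significance is a
  Mantel-style permutation of individual labels (default 999;
  p = (1 + #{|β_perm| ≥ |β_obs|})/(1 + permutations)) because pairs are not
  independent; the naive OLS p is reported alongside but should not be
  trusted.  Natural log throughout (base only rescales β).

## Comparative layer

Pagel's λ is profiled by ML over [0, λ_max]; λ_max (≤ 1.1, so estimates
slightly above 1 remain reachable) is bounded by a conditioning floor
(smallest eigenvalue of V(λ) above 1e-3 of the mean tip variance) rather
than the raw positive-definiteness boundary, because the profile likelihood
diverges spuriously as V(λ) approaches singularity and would otherwise park
λ̂ on the boundary with meaningless standard errors.  The λ p-value is a
χ²₁ likelihood-ratio test against λ = 0; Blomberg's K uses the standard
ratio form with a one-sided (≥) tip-shuffling permutation p.  PGLS profiles
λ by ML and fits GLS with V(λ̂); at λ = 0 it reproduces OLS exactly.  VIF
elimination iteratively drops the worst predictor (ties by column order;
perfect collinearity drops first with an infinite-VIF note) until all
VIF < 10.  Tip rates are log-transformed before signal tests and PGLS by
default (raw-scale switch provided); tip rate is the PGLS response.  No
multiple-testing correction is applied to the headline tests (raw p-values
are primary); a Benjamini–Hochberg column is emitted alongside for
transparency.  Species are matched to tree tips by exact label with an
optional alias map — no fuzzy matching, since silent mismatches are the
main practical failure mode of comparative tables.

## Problem sizes

The validation experiments use: 20 trajectory draws for the congruence
invariant; 100 trees (≥ 200 tips) for the pulled-rate oracle; 100
replicates for the declining-trend experiment; 100 seeds per arm for β_IBD
recovery (n = 20, 5000 sites), Mantel calibration (999 permutations), and
each coupled/uncoupled world arm; 200 seeds for Blomberg-K calibration and
100 for Pagel-λ recovery.  These sizes give Monte-Carlo standard errors
well inside the tolerances they are checked against.
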