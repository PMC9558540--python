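# Methods

## Model

`threshlin` fits a three-trait animal model to kit-level records from a
small rabbit breeding population:

    y = Xb + Za + Wm + Vc + e

per trait, where the traits are survival at birth (SB), survival at weaning
(SW) and individual birth weight (BW, grams).  The two survival traits are
binary and modelled on an underlying Gaussian liability scale: a kit is
observed alive if its latent liability exceeds a threshold.  Jointly the
random effects are

* `a` — direct additive genetic values, one 3-vector per pedigree animal,
  `a ~ N(0, A ⊗ G0)` with `A` the numerator relationship matrix;
* `m` — maternal permanent environmental effects, one per doe,
  `m ~ N(0, I ⊗ M0)`;
* `c` — common litter effects, one per litter, `c ~ N(0, I ⊗ C0)`;
* `e` — residuals, `e ~ N(0, I ⊗ R0)`.

Fixed effects are parity (1–3), lactation status at mating, season of
farrowing, nest quality, cannibalism, place of birth relative to the nest,
and sex, with drop-first reference coding over the observed levels plus a
per-trait intercept.  Optionally the total number of kits born enters every
trait as a centred linear covariate (`adjust_for_litter_size`); centring
keeps the covariate orthogonal to the intercept.

Reported quantities are computed per posterior draw and then averaged:
phenotypic variance `P_t = g_tt + m_tt + c_tt + r_tt`, heritability
`h² = g_tt/P_t`, maternal fraction `m² = m_tt/P_t`, litter fraction
`c² = c_tt/P_t`, and the correlation families `r_g`, `r_m`, `r_c` on the
component matrices plus the phenotypic
`r_p = (g_ts + m_ts + c_ts + r_ts)/√(P_t P_s)`.  The heritability
denominator deliberately includes all four components; the reported
fractions per trait therefore sum to one with the residual fraction.

## Identifiability of the threshold traits

A binary trait fixes neither the location nor the scale of its liability.
The sampler pins the threshold at 0 and the residual liability variance at
exactly 1.  The variance constraint is enforced by *draw-then-standardize*:
after each unconstrained inverse Wishart draw of `R0`, the matrix is
rescaled to unit liability diagonals and the same factors are applied to
the liabilities, the residuals, the corresponding columns of `b, a, m, c`
and the rows/columns of `G0, M0, C0`.  The transformation is a
deterministic reparameterisation of an invariant direction of the
posterior, so every standardized residual is unchanged.

The residual covariance between the two survival liabilities is fixed at 0:
SW is only recorded for kits alive at birth, so the likelihood carries
essentially no information about it and leaving it free would add an
unidentified random walk to the chain.  The residual covariances of each
survival trait with BW are sampled (identified through kits observed on
both).  After zeroing, positive definiteness is re-checked and, in the
(never observed in practice) failure case, the remaining off-diagonals are
shrunk by 10% until the Cholesky succeeds.

## Gibbs sampler

One iteration performs:

1. **Liability augmentation** — every binary cell is redrawn from a normal
   conditional (mean = fitted value plus the residual regression on the
   kit's other-trait residuals through `R0⁻¹`), truncated below/above 0 by
   the observed category; missing cells (SW of kits dead at birth, missing
   BW) are drawn untruncated, which keeps all covariance updates
   complete-data.  Tail truncation uses Robert's exponential rejection
   sampler, robust to means many standard deviations past the threshold.
2. **Location effects** — single-site Gauss–Seidel draws of every fixed
   effect (flat prior, optionally bounded), additive value (prior precision
   `A⁻¹ ⊗ G0⁻¹`, assembled sparsely by Henderson's rules with inbreeding),
   maternal and litter effect.  A residual matrix is kept consistent
   incrementally.  These sweeps are numba-compiled.
3. **Covariance matrices** — conjugate inverse Wishart draws for `G0`
   (scale `a'A⁻¹a` + prior, df = animals + prior df), `M0`, `C0`.
4. **Scale moves** — see below.
5. **Residual matrix** — inverse Wishart draw from the augmented residual
   cross-products, then the standardization step.

The chain owns a single seeded generator (the numba kernels' stream is
seeded once from the same root seed), so runs are bitwise reproducible.

### Block updates

Two exact joint updates supplement the scalar sweeps, because two
directions of the posterior decorrelate very slowly under single-site
sampling:

* **Additive-genetic block** (every `block_a_every`-th iteration, default
  5): all animals' breeding values are redrawn jointly from their exact
  multivariate conditional by solving the genetic block of the mixed-model
  equations, using the sampling-by-perturbation identity (solve once for
  the conditional mean, once for a perturbed system built from a prior
  pedigree draw and synthetic residuals; the difference has exactly the
  conditional covariance).  The precision `G0⁻¹ ⊗ A⁻¹ + R0⁻¹ ⊗
  diag(records)` factors with almost no fill under a symmetric
  minimum-degree ordering, so one update costs two sparse solves.  Without
  this step the exchange between the genetic covariance and the a-field
  has autocorrelation times of 10⁴⁺ iterations and reduced-chain
  heritability estimates are dominated by chain noise.
* **Per-doe maternal/litter blocks** (every iteration): a doe's maternal
  effect and all her litters' effects are redrawn jointly from their exact
  (1 + litters) × traits Gaussian conditional; does are conditionally
  independent, so this is a cheap loop of small Cholesky solves.  The m/c
  split is near-exchangeable at ~2.6 litters per doe and scalar updates
  can stick in a mis-attributed mode.

Both block updates were validated against brute-force dense conditionals
(moment match) and leave all single-site results unchanged.

### Parameter-expansion scale moves

Single-site samplers of variance components have a well-known failure mode:
when a component's variance is drawn small, its effects are shrunk toward
zero, which makes the next variance draw smaller still.  With a prior whose
scale is far below the trait's variance this becomes a quasi-absorbing
state.  The sampler therefore adds, each iteration and for each of the
`a`/`m`/`c` blocks and each trait, a group scale move: a multiplicative
factor α is applied jointly to the whole effect column and to the
corresponding row/column of its covariance matrix, with α drawn from the
exact conditional implied by the multiplicative-group transformation under
Haar measure (the prior-density and Jacobian terms cancel against each
other except for an `α^(−ν−1)` factor and the Wishart-scale term).  The
one-dimensional density is sampled by slice sampling.  The move leaves the
posterior invariant and was validated two ways: a prior-only chain
reproduces the prior marginals, and posterior means/SDs match an
independent dense joint-update Gibbs implementation on a single-trait
dataset.  In flat-prior mode the move's density is improper and the move is
skipped.

## Priors

Covariance matrices get proper, weakly informative inverse Wishart priors:
df = 5 and diagonal scale equal to 5% of each trait's observed phenotypic
variance for `G0`, `M0`, `C0`, and 50% for `R0` (liability traits use scale
1, their fixed residual variance).  Scaling the prior to the trait is
essential, not cosmetic: a fixed small scale (say 0.01) on a trait whose
variance is in the hundreds of g² puts essentially all prior mass near
zero, and the collapse described above then occurs for *any* correct
sampler — we reproduced it with an independent exact implementation.
Fixed effects have flat (optionally bounded uniform) priors.  A
`flat=True` mode provides the improper reference prior for the covariance
matrices; it is intended for the well-identified oracle settings in the
test-suite, not for small binary-trait datasets, where posterior propriety
is at risk.

## Posterior summaries

* **95% HPD** — shortest contiguous window containing ⌈0.95 n⌉ sorted
  draws; ties go to the lowest-start window.
* **Sign probabilities** — strict empirical fractions of draws above/below
  zero.
* **Geweke Z** — first 10% vs last 50% of the chain, variances estimated by
  the spectral density at zero from an AR(p) fit (Yule–Walker, AIC order up
  to 10).  |Z| > 3 raises a convergence flag.
* **MCSE** — batch means with ⌊√n⌋ batches.

Summaries require at least 100 saved draws; Geweke needs 200.

## Synthetic-data generator

The generator emulates the study population whose raw records are not
deposited: 81 does mated over 3 parities, a farrowing-failure thinning of
0.85 litters realized per mating (reconciling 81×3 matings with ~208
litters), litter sizes `round(N(8.15, 3.16²))` truncated at 1, and ~1,700
kits.  Founder bucks default to 40 (a 1:2 mating ratio typical of a small
nucleus line; total pedigree ≈ 1,920 animals).  Pedigrees contain founders
only; kits are linked to their sire, dam and litter.

True covariance matrices are assembled from the reported phenotypic
fractions (per trait h², m², c²; liability traits have residual variance 1,
so `P = 1/(1 − h² − m² − c²)`; BW uses phenotypic SD 15.19 g) and the
reported component correlations.  Residual covariances of SB/SW with BW are
backed out from the reported *phenotypic* correlations
(`r_p·√(P_t P_s) − g_ts − m_ts − c_ts`), giving residual correlations of
about 0.32 (SB–BW) and 0.23 (SW–BW); the SB–SW residual covariance is 0 by
construction.  Any non-PSD combination is repaired by shrinking
off-diagonals with a warning.

Breeding values descend the pedigree by Mendelian sampling: founders draw
`N(0, G0)`, offspring get the parent average plus a deviation with
covariance `0.5·(1 − (F_s + F_d)/2)·G0`.  Latent trait values add the
intercept, fixed effects, `a`, `m`, `c` and a residual draw; SB thresholds
at 0, SW is generated only for kits alive at birth (dead kits carry the
missing code), and BW is clamped at 1 g (affects well under 0.1% of kits).
Intercepts are calibrated analytically — probit of the target survival
rates times the liability SD, and the target BW mean — net of the expected
fixed-effect contribution under the configured level frequencies.

Default fixed-effect values are qualitative readings of the published
level differences (parity-1 kits ≈ 8 g lighter than parity-3, summer and
lactating-doe deficits, females ≈ 1 g lighter), scaled so that the total
fixed-effect variance stays small against the component variance; they are
configuration, not asserted study truth.  The default litter-size
coefficient is zero so that the unadjusted variance fractions are exactly
the generator's truth.

What the generator does *not* emulate: selection response, seasonal
temperature structure, nonlinear birth-weight–survival association,
cross-fostering, maternal *genetic* effects (the maternal term is permanent
environment, as in the model), and ancestry beyond the founder generation.
Passing recovery tests therefore demonstrate correct inference under the
model's own assumptions at the study's scale — not robustness to real-data
violations of them.

## Problem sizes and chain lengths

The full protocol (1,000,000 iterations, 500,000 burn-in, thin 100 — 5,000
saved samples) is the class default.  With the block updates the reduced
chains used by the test-suite and the acceptance script are adequate:
40,000 / 10,000 / 20 for the study-scale fit and 20,000–40,000 with
proportional burn-in for the larger (~3,000 and ~5,000 kit) datasets,
each a few minutes on one CPU.  Oracle tests run in seconds.

## Known limitations

* Heritability at study scale (~208 litters, 40 sires) is weakly
  identified; its posterior is wide (the corresponding published interval
  spans 0.006–0.234) and posterior means vary noticeably between simulated
  datasets.  The litter fractions and litter-effect correlations are much
  better determined.
* Maternal (m²) and litter (c²) fractions separate only through repeat
  litters per doe (~2.6 here), so some m/c exchange is visible at study
  scale.  For the liability traits this decomposition is markedly
  dataset-sensitive even at ~600 litters: binary outcomes at ~90% survival
  carry a small fraction of the information in the underlying latents (a
  Gaussian fit of the same latents pins the components far more tightly),
  and posterior means of c² for survival can sit ~2 posterior SDs from the
  generating value for unlucky datasets.
* Single-site location updates are memory-light but serially correlated;
  block updates would shorten chains at the cost of a sparse solver per
  iteration.
* The threshold traits assume exactly two categories; multi-threshold
  extensions are out of scope.
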