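# threshlin

Bayesian **threshold–linear animal model** for neonatal survival and birth
weight in rabbit kits — for quantitative geneticists and breeding-program
analysts who want to estimate direct genetic, maternal permanent
environmental and common litter (co)variance components from kit-level
records and a pedigree.

## The model

Survival at birth (SB) and at weaning (SW) are binary traits modelled on an
underlying liability scale; individual birth weight (BW, g) is Gaussian.
Jointly, per trait,

```
y = Xb + Za + Wm + Vc + e
```

with

```
a ~ N(0, A ⊗ G0)     direct additive genetic (A = pedigree relationship matrix)
m ~ N(0, I ⊗ M0)     maternal permanent environmental (per doe)
c ~ N(0, I ⊗ C0)     common litter (per litter)
e ~ N(0, I ⊗ R0)     residual
```

`G0, M0, C0, R0` are 3×3 covariance matrices estimated by Gibbs sampling
with liability augmentation (truncated-normal draws at the fixed zero
threshold, residual liability variance fixed at 1).  Reported parameters:
heritability `h²_t = g_tt / P_t` with `P_t = g_tt + m_tt + c_tt + r_tt`,
maternal and litter fractions `m²_t`, `c²_t`, and the correlation families
`r_g`, `r_m`, `r_c`, `r_p`, each with posterior mean, 95% HPD interval,
sign probabilities, Geweke Z and Monte Carlo standard error.  A synthetic
data generator reproduces the study structure (81 does, 3 parities, ~208
litters, ~1,700 kits, ~90.6% survival at birth, birth weight
51.4 ± 15.2 g), so the whole pipeline is testable by parameter recovery.
See `docs/methods.md` for the sampler and calibration details.

## Worked example

```python
from threshlin import SimConfig, simulate, ThresholdLinearModel, summarize_dataset

ped, records, truth = simulate(SimConfig(seed=1))
print(summarize_dataset(records))

model = ThresholdLinearModel(n_iter=20_000, burn_in=5_000, thin=10, seed=1)
model.fit(records, ped)
print(model.report())
```

prints the descriptive summary of the simulated dataset

```
birth weight, all kits (g)         n= 1649 mean=  49.08 sd= 15.54
birth weight, live kits (g)        n= 1477 mean=  49.96 sd= 15.29
birth weight, dead kits (g)        n=  172 mean=  41.48 sd= 15.68
kits born per litter               n=  206 mean=   8.00 sd=  3.25
kits born alive per litter         n=  206 mean=   7.17 sd=  3.19
kits weaned per litter             n=  206 mean=   6.29 sd=  2.99
survival at birth:   89.57%
survival at weaning: 87.75%
```

and triangular tables of posterior means with 95% HPD intervals, e.g. the
common-litter block (litter fractions on the diagonal, litter-effect
correlations above it):

```
common litter (c2 diag, r_c above)
	SB	SW	BW
SB	+0.128 [0.024, 0.236]	-0.091 [-0.675, 0.808]	+0.758 [0.487, 0.982]
SW		+0.157 [0.023, 0.280]	+0.407 [0.039, 0.833]
BW			+0.357 [0.248, 0.448]
```

Here the litter fraction for birth weight is estimated at 0.36 against a
generator truth of 0.435 (the heritability, 0.080, lands next to its truth
of 0.088) — at ~206 litters the realized litter variance of a single
dataset wanders this much, which is exactly why the posterior intervals
are wide.  `model.breeding_values_` holds posterior-mean additive
genetic values for every pedigree animal, and
`model.samples_.save("trace.tsv")` writes the full thinned trace.

The same pipeline runs from the shell:

```
threshlin simulate --config run.yaml     # pedigree.txt, phenotypes.csv, truth.txt
threshlin fit      --config run.yaml     # posterior trace + convergence log
threshlin summarize --trace out/trace.tsv --out out/report
```

All randomness flows from the single `seed` key in the YAML config; a rerun
with the same seed is byte-identical.

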