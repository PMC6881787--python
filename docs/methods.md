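# Methods

## Trial designs and data model

An inoculation trial crosses a panel of bean genotypes with a panel of
rhizobium strains in a randomized complete block design; replicate is the
blocking factor. Every genotype additionally carries one *negative*
control treatment (uninoculated, unfertilised — the N-difference baseline)
and one *positive* control treatment (uninoculated, KNO3-fed — the yield
ceiling), each replicated like a strain treatment. The unit count is
therefore `(g·s + g·(pos+neg))·r`: 500 for the reference jar layout
(10 × 8 × 5, 1+1 controls) and 200 for the pot layout (5 × 6 × 5, 1+1).
Treating the controls as per-genotype treatments is the only scheme under
which those totals balance.

Nitrogen dosing arithmetic uses the N mass fraction of KNO3 from standard
atomic masses, 14.0067/101.1032 ≈ 0.13854, so a 0.5 g/L solution carries
0.06927 g N/L. (A pot-feeding note sometimes quoted as "10 g/L KNO3 of
which N is 0.140067 g/L" is inconsistent with that mass fraction — 10 g/L
carries 1.3854 g N/L — and is not reproduced here.)

One row per plant: factors (experiment, genotype, treatment, replicate)
and phenotypes (nod, fix, nodule number, nodule dry weight, shoot dry
weight, optional shoot %N). Invariants enforced on read: nod = 0 forces
fix = 0 and nodule_number = 0; weights non-negative; %N in [0, 100];
missing %N is an explicit NaN, never imputed — operations that need it
fail loudly.

## Symbiosis metrics

All metrics are normalised within genotype, because bean genotypes differ
strongly in seed size and inherent vigour:

- TSN = SDW · %N/100 (g).
- Ndfa = TSN_inoculated − mean TSN of the genotype's negative controls
  (N-difference method). May be negative; reported as-is so downstream
  ANOVA noise stays symmetric.
- RNdfa = Ndfa / mean TSN of the positive controls.
- RSE (≡ RSDW) = (SDW_inoculated − mean SDW_neg) / mean SDW_pos. The
  positive-control denominator is used instead of the classical
  (pos − neg) difference, whose near-zero values under replicate noise
  produce a badly skewed ratio; the RSDW analysed throughout is exactly
  this quantity.

Control means are genotype-level (pooled over replicates) by default;
replicate-matched pairing is available but not default, since the
normalising quantities are genotype properties.

Score matrices for heat-maps hold per-cell means scaled to the observation
scale: for binary nod/fix the cell value is the proportion of positive
plants (already in [0, 1]); for RSDW, cell means are min–max scaled over
the observed matrix. Empty cells are missing, not zero.

## Factorial RCBD ANOVA

For a balanced g × s × r layout the sequential (type I) sums of squares
are computed in closed form from marginal totals; Rep, Genotype, Strain
and Genotype × Strain are mutually orthogonal on balanced data, so the
order among the factor terms is immaterial (verified against explicit
sequential model fits in the test suite). Fixed-effect F tests use the
residual mean square. The original analyses of such trials typically fit a
mixed model with a random replicate effect (REML, Satterthwaite df); for a
balanced RCBD the fixed-effect F statistics of that model coincide with
this classical decomposition, which is exact, dependency-free and fast —
that equivalence is why no REML machinery is included.

Unbalanced data: hard error by default. An optional imputation path
replaces missing plots by their cell mean and subtracts the number imputed
from the residual df; wholly empty cells always error. p-values are
unadjusted across responses, as is conventional for these trials; stars
follow the usual legend (*** < 0.001, ** < 0.01, * < 0.05, . < 0.1).

The group-contrast model nests genotypes in groups (genepool, growth
habit, country of origin):

    y = Rep + Group + Genotype(Group) + Strain + Group×Strain
        + Genotype×Strain(Group) + residual

Groups may hold unequal numbers of genotypes; the per-group totals are
weighted accordingly, and the partitions Group + Genotype(Group) =
Genotype and Group×Strain + Genotype×Strain(Group) = Genotype×Strain hold
exactly. Expected-mean-squares tests treat the genotype terms as random:
Group is tested against Genotype(Group), Strain and Group×Strain against
Genotype×Strain(Group). A stratum with 0 df (e.g. every group holding a
single genotype) renders the contrast untestable — F and p are reported
as None, never silently dropped. Under a null where genotype effects are
drawn iid irrespective of group, the Group test holds its nominal level
(checked by simulation).

## AMMI decomposition

Cell means are arranged strains × genotypes — strains play the classical
"genotype" role and bean genotypes the "environment" role, so biplot
patterns read as strain adaptation across host genotypes. Double centering
removes μ, row and column effects; the residual interaction matrix Z (rows
and columns summing to zero) is decomposed by SVD. Conventions:

- Axis SS on the plot level: SS_k = r·λ_k², so Σ_k SS_k equals the
  factorial-ANOVA interaction SS exactly (a cross-module invariant tested
  at 1e-8 relative tolerance). r = 1 when only means are available.
- Axis df by Gollob's rule, g + e − 1 − 2k — the only rule consistent
  with the reference tables' printed values; the dfs telescope to
  (g−1)(e−1).
- Axis F = (SS_k/df_k)/residual MS of the matching ANOVA. Gollob's test
  is liberal under the null (first-axis rejection well above nominal in
  simulation); it is used descriptively, to rank axes, not for strict
  error control.
- Sign ambiguity: the largest-magnitude element of each left singular
  vector is made positive. Singular-value ties are broken by the
  decomposition order, which is deterministic for a fixed backend.
- Biplots use symmetric scaling (scores × √λ_k, k = 1, 2); two retained
  axes by default, all axes always available. A numerically zero second
  singular value is flagged degenerate and its coordinates zeroed.

## Synthetic trials

The generator emulates the study conditions on the shoot-dry-weight scale
(grams):

    sdw = μ + α_i + β_j + Σ_k λ_k ξ_ik η_kj + rep_b + ε,   ε ~ N(0, σ²)

with ξ, η drawn once per seed as random orthonormal score sets orthogonal
to the ones vector, so the simulated interaction is exactly
double-centered by construction. Defaults (chosen once as realistic jar
conditions): μ = 2.0 g; strain effects spanning +0.45 (a strongly
effective *R. tropici*-like strain) to −0.65 (non-nodulating strains),
summing to zero; genotype effects proportional to 100-seed weight
(0.012 g per g, centered), reflecting seed-size-driven vigour; λ = (1.5,
0.8) in jars and (0.75, 0.4) in pots (interaction was weaker in pots);
block sd 0.1; plot noise sd 0.25. Negative controls receive μ + β_j minus
a fixed inoculation benefit (0.4 g); positive controls an elevated N-fed
mean (2.8 g) common to all genotypes — under these settings effective
strains land at RSE ≈ 0.1–0.5, within the range reported for such
screenings. Binary phenotypes follow a logistic link in the latent strain
effectiveness α_i + interaction: nodulation probability
expit(logit(0.9) + 4·latent) and fixation probability expit(4·latent), so
weakly effective strains produce the characteristic nod+/fix− pattern and
the non-nodulators nodulate inconsistently. Nodule counts are Poisson
given nodulation; shoot %N (pot trials) rises with effectiveness
(2.5 + latent, vs 1.5 for negative and 3.5 for positive controls), making
Ndfa positive in expectation for effective strains.

Randomness: a single root seed; each unit draws from a child stream keyed
by a hash of its (genotype, treatment) labels plus replicate, and block
effects from a separate stream — so subsetting a design leaves the
remaining units' draws bit-identical (tested). Identical config + seed
gives identical tables.

What the generator does *not* emulate: strain competition and co-occupancy
of nodules, soil/greenhouse environmental gradients beyond a scalar block
effect, genotype-specific control ceilings (the positive-control mean is
common across genotypes, which makes RSDW exactly additive when the truth
is additive), non-Gaussian or heteroscedastic biomass noise, and
measurement error in %N calibration. Passing tests therefore demonstrate
the correctness and calibration of the estimators under the stated model,
not robustness to those real-data features. Shoot biomass is Gaussian and
clipped at zero as a guard; with default effect sizes the clip is
essentially never active.

## Numerical notes and limitations

- Balanced-ANOVA SS are computed from marginal totals; cancellation
  leaves absolute errors of order 1e-12 on totals of order 10³, so "zero"
  SS assertions use 1e-9 absolute tolerance.
- Sample singular values of a noisy matrix are inflated upward by
  O(σ²/λ) (the noise occupies all directions); at jar scale (cell-mean
  noise ≈ 0.045 g) this bias is ≈ +0.01 on a singular value of 1 — small
  relative to the estimate's own sampling sd (≈ 0.05) but systematic.
  Recovery checks compare medians to truth on the scale of the estimates'
  Monte-Carlo spread.
- Gollob axis tests are liberal; treat axis significance as descriptive.
- The imputation path is a convenience for near-balanced data, not a
  missing-data method; more than a few missing plots warrant a mixed
  model instead.
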