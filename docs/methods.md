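# Methods

This note documents the models, conventions and numerical choices behind
`qsarscreen`, and what the synthetic-data tests do and do not establish
about behaviour on real descriptor matrices.

## The modelling problem

The package targets the classical small-data QSAR regime: n ≈ 35–50
compounds with measured activity (pIC50 = −log10 IC50), p ≈ tens to
hundreds of candidate molecular descriptors, and a linear model

    ŷ = b0 + Σ_j b_j x_j

on a small selected subset (k ≈ n/4 or fewer). Everything downstream —
cross-validation, external validation, applicability domain — exists
because at this sample size a well-fitting model is easy to obtain by
chance and hard to trust.

## Descriptors

**RDF codes.** g(r) = f · Σ_{i<j} A_i A_j exp(−B(r−r_ij)²) over all
unordered atom pairs, with r_ij the Euclidean interatomic distance. The
radius grid follows the common descriptor-suite naming convention
(label/10 = radius in Å; default grid 0.5–15.5 Å in 0.5 Å steps);
defaults B = 100 Å⁻², f = 1, both configurable, since published software
does not document its exact values. g(r) is invariant under rigid motion
and atom relabelling by construction; the test suite asserts both to
1e-10 under random rotations/translations/permutations.

**MATS / GATS.** Moran and Geary autocorrelations of an atomic property
w over the molecular graph at topological lag d (shortest bond-path
length), using ordered-pair counting Δ = #{(i,j): d_ij = lag}:

    MATS = [(1/Δ) Σ_{d_ij=lag} (w_i−w̄)(w_j−w̄)] / [(1/N) Σ_i (w_i−w̄)²]
    GATS = [(1/(2Δ)) Σ_{d_ij=lag} (w_i−w_j)²] / [(1/(N−1)) Σ_i (w_i−w̄)²]

Zero-variance weights and lags with no realizing pair return 0 rather
than erroring, keeping batch computation total. An independent
double-loop oracle in the tests agrees to 1e-12.

**Weights.** Atomic properties are carbon-scaled (value/value-of-carbon),
so carbon has weight 1 in every scheme and the unweighted scheme maps all
elements to 1. Shipped tables: standard atomic masses, Bondi-radius van
der Waals volumes (4/3·π·r³), Sanderson electronegativities, atomic
polarizabilities. The exact tables used by commercial descriptor software
are unpublished; these common published values are the default and any
custom `WeightScheme` can replace them, so bit-exact agreement with
third-party software on real molecules is explicitly not a goal.

**C-005.** Count of CH3 carbons whose single heavy neighbour is in
{O, N, S, P, Se, F, Cl, Br, I}. When a structure carries no explicit
hydrogens anywhere, implicit H counts are inferred from standard
valences under a single-bond assumption; files with explicit hydrogens
are taken literally.

**MATS/GATS vs RDF distance.** Autocorrelations use topological
(bond-count) distance because they are 2-D descriptors; RDF uses 3-D
geometry. SDF input is read via RDKit with coordinates taken verbatim —
no conformer generation or geometry optimization.

## Data preparation

* Constant filter: zero-variance columns always drop; a column whose
  modal value occupies ≥ 95 % of rows (default) drops as near-constant.
* Collinearity filter: pairs with |Pearson r| above the threshold
  (default 0.9) are processed in descending |r|; in each pair the member
  with the lower |correlation to activity| is removed, skipping columns
  already gone. The survivor set is verified to contain no pair above
  the threshold.
* Kennard-Stone: distances are Euclidean in autoscaled (zero-mean,
  unit-variance) descriptor space, so large-magnitude descriptors do not
  dominate. The seed pair realizes the exact maximum pairwise distance;
  each later pick maximizes the minimum distance to the selected set.
  Ties are broken by the lexicographically smallest standardized row,
  then the smallest original index — this makes the selected *compounds*
  invariant to row order whenever rows are distinct.

## Modelling

OLS is solved by QR decomposition; coefficient standard errors come from
(XᵀX)⁻¹·MSE. Leave-one-out statistics use the exact hat-matrix identity
e_(i) = e_i/(1−h_ii): PRESS = Σ e_(i)², Q² = 1 − PRESS/SStot,
RMScv = √(PRESS/n). Q² uses the full-training-set mean in its
denominator. A leverage of 1 makes leave-one-out degenerate and raises an
error. Rank-deficient designs are rejected with the dependent columns
named (pivoted QR). For constant activity (SStot = 0) the
variance-explained statistics are reported as 0.

**Stepwise.** Forward steps add the candidate with the smallest
partial-F p-value (t² of the entering coefficient against F(1, n−k−2)) if
below `p_enter` (default 0.05); backward steps remove the included
descriptor with the largest p-value if above `p_remove` (default 0.10);
cycles alternate until stable or `max_steps`. At p ≫ n unbounded forward
selection will saturate the design (the minimum p-value over hundreds of
null candidates stays below 0.05 essentially forever), so a step cap —
used as 8 cycles in the acceptance pipeline, matching an 8-descriptor
target model — is the practical guard.

**Genetic algorithm.** Chromosomes are inclusion bitstrings; fitness is
LOO RMScv (lower better), memoized per subset; chromosomes with zero or
more than `max_descriptors` bits (default ⌊n/4⌋, a guard against
overfitted subsets) get infinite fitness. Selection is a size-2
tournament; crossover is uniform, applied with probability ramping
linearly 90 → 60 % across generations; per-bit mutation ramps 0 → 1 %.
The published descriptions of such GAs give the rate *ranges* but not the
ramp direction; rising mutation was chosen to fight late premature
convergence, and both endpoints are configurable so the opposite reading
is expressible. Elitism keeps the single best chromosome. The run stops
when 90 % of the population shares the best fitness (to 1e-12) or at
`max_generations`. Initial chromosomes draw a subset size uniformly from
[1, max_descriptors] so the starting population is valid. All randomness
flows from `GAConfig.seed`.

## Validation conventions

* R²pred is the squared Pearson correlation of predicted vs observed on
  the external set; the alternative Q²ext = 1 − SSres/SStot is reported
  as an auxiliary field but takes no part in the pass rules.
* Through-origin statistics: k = Σyŷ/Σŷ² with
  R0² = 1 − Σ(y−kŷ)²/Σ(y−ȳ)², and the primed pair with y and ŷ swapped.
  Several literature variants exist; this one is pinned and unit-tested.
* rm² = R²pred·(1 − √|R²pred − R0²|). The absolute value is required:
  R0² frequently exceeds R²pred (both roles of the rule's "close to"
  test), making the unsigned difference negative. Numerically, the
  square root amplifies machine epsilon, so even a perfect
  prediction yields rm² = 1 − O(1e-8), not 1 − O(1e-16); tests allow
  1e-7 there and 1e-12 elsewhere.
* Pass rules: Q² > 0.5, R²pred > 0.6, |(R²pred−R0²)/R²pred| < 0.1 *or*
  the R′0² analogue, 0.85 ≤ K ≤ 1.15 *or* 0.85 ≤ K′ ≤ 1.15, rm² > 0.5.
  The overall verdict is the conjunction.
* Applicability domain: leverage h = x(XᵀX)⁻¹xᵀ on intercept-augmented
  rows against the stored training design; h* = 3(k+1)/n; the inside
  test is strict (h < h*, boundary counts as outside). Standardized
  residuals r_i = e_i/(SE·√(1−h_ii)) flag |r| > 2.5 strictly. For an
  exact fit (SE ≤ 1e-12·scale) residuals are reported as exact zeros
  rather than ratios of roundoff.
* Y-randomization shuffles the activity vector with a seeded permutation
  per repetition and rebuilds a model either on a fixed descriptor set
  (`refit_fixed`, fast) or by rerunning the selection procedure
  (`rerun_stepwise`/`rerun_ga`, the stricter reading — a scrambled run
  should be given the same chance to overfit the original run had).

## The synthetic generator

`generate_dataset` emulates the study conditions: 46 compounds × 300
descriptors by default, 8 active standard-normal columns with
coefficients of magnitude 0.5–1.5 and random sign (drawn once from the
seed), intercept 5.0 pIC50 units, Gaussian activity noise of sd 0.3,
plus 5 collinear pairs (partner x′ = r·x + √(1−r²)·z, r = 0.95, redrawn
until the sample correlation is within ±0.05) and 3 constant columns.
One `numpy` Generator seeded by a single integer drives everything, so a
fixed spec reproduces byte-identical tables.

What it does *not* emulate: real descriptor marginal distributions
(heavy tails, integer counts, block correlation structure), descriptor–
descriptor correlations beyond the planted pairs, and any nonlinearity
or activity cliffs. Passing tests therefore demonstrate algorithmic
correctness and statistical behaviour under a clean linear model — not
that any particular real dataset will yield a predictive model.

## Selection at p ≫ n: an honest caveat

With 8 equal-magnitude active columns among ~290 candidates and only 35
training compounds, each active column individually explains ~13 % of
the activity variance, while the maximum chance correlation among the
noise columns is larger. Greedy stepwise and a 200-generation GA
therefore typically select chance correlates: the resulting model shows
excellent internal statistics (R² ≈ 0.9, Q² ≈ 0.85) yet fails external
validation (R²pred ≈ 0.1) — exactly the failure mode the
Golbraikh–Tropsha rules and Y-randomization are designed to expose, and
the pipeline reports it as such. The acceptance script therefore also
reports (a) the reference model fit on the generator's known active
columns, which passes externally (R²pred ≈ 0.99), and (b) a full
pipeline run at 46 × 40 where selection is identifiable and the selected
model passes all rules. Problem sizes throughout (20 LOO fixtures with
n ≤ 50, k ≤ 10; GA recovery on 46 × 40 with 5 seeds; 200 Y-randomization
scrambles at n = 35, k = 8; 50 Kennard-Stone instances) were chosen as
the smallest sizes at which the corresponding properties are
statistically meaningful.

## Known limitations

* MLR only — no PLS, ridge/lasso or nonlinear learners by design.
* No conformer generation or geometry optimization; RDF values depend on
  the 3-D coordinates supplied.
* Quantum-chemical, logP, hydration-energy, volume and surface-area
  descriptors are not computed; they enter as precomputed columns.
* Descriptor values are not bit-compatible with commercial software
  (unpublished parameter tables and grids).
* The collinearity filter is greedy; it guarantees no surviving pair
  above the threshold but not a globally optimal survivor set.
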