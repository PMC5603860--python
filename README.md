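# qsarscreen

Descriptor-based QSAR modelling and in-silico screening for small
bioactivity datasets, built around the workflow used to model IL-1β
production inhibition of pyridazine derivatives: a few dozen compounds,
hundreds of candidate molecular descriptors, a multiple-linear-regression
(MLR) model on a handful of them, and a battery of validation checks
before the model is let loose on designed candidate structures.

It is aimed at medicinal/computational chemists who want a transparent,
fully scriptable MLR pipeline — every stage is a plain function over a
compound-by-descriptor table, and every statistic is recomputable.

## What it does

**Descriptors.** Radial distribution function (RDF) codes from 3-D
coordinates,

    g(r) = f · Σ_{i<j} A_i A_j · exp(−B (r − r_ij)²),

evaluated on a fixed radius grid (name convention `RDF105u` → r = 10.5 Å,
unweighted); Moran and Geary autocorrelations (`MATS#w`, `GATS#w`) of
carbon-scaled atomic properties (mass, van der Waals volume, Sanderson
electronegativity, polarizability) over the molecular graph at a
topological lag; and the Ghose–Crippen `C-005` fragment count (CH3 bonded
to an electronegative atom). Quantum-chemical and surface-area
descriptors are accepted as precomputed CSV columns.

**Data preparation.** Constant/near-constant column removal; pairwise
collinearity pruning (for |r| > 0.9 the member better correlated with
activity is kept); Kennard-Stone max–min-distance splitting into training
and prediction sets.

**Modelling.** OLS with intercept; R², adjusted R², F, SE; leave-one-out
Q², RMScv and PRESS via the hat-matrix shortcut e_i/(1−h_ii); stepwise
selection on partial-F probabilities (enter 0.05 / remove 0.10); a
genetic algorithm over descriptor-inclusion bitstrings (population 100,
uniform crossover ramping 90→60 %, per-bit mutation ramping 0→1 %,
tournament selection, elitism 1) with LOO RMScv as fitness; VIF and
standardized-residual diagnostics (|r| > 2.5 flags outliers).

**Validation.** Golbraikh–Tropsha external criteria (Q² > 0.5,
R²pred > 0.6, through-origin R0²/R′0² closeness, slopes K/K′ in
[0.85, 1.15]) plus Roy's rm² = R²pred·(1 − √|R²pred − R0²|) > 0.5;
Y-randomization (activity scrambling with model refits); leverage
applicability domain with warning threshold h* = 3(k+1)/n and
Williams-plot export.

**Screening.** Predict candidate activities, attach leverage and
in-domain flags (never silently dropping out-of-domain candidates), and
rank by predicted pIC50.

A synthetic-data generator produces descriptor matrices with planted
linear signals, collinear pairs and constant columns, so the whole
pipeline is testable with known ground truth.

## Worked example

Generate a 46-compound, 40-descriptor matrix with 5 active descriptors
(noise 0.2 pIC50 units), reduce it, split 35/11 by Kennard-Stone, select
descriptors by GA, and validate externally:

```python
from qsarscreen import (
    SyntheticSpec, generate_dataset, remove_constant, collinearity_filter,
    kennard_stone_split, ga_select, GAConfig, external_validate,
    tropsha_check, predict, screen,
)

spec = SyntheticSpec(n_compounds=46, n_descriptors=40, n_active=5,
                     noise_sd=0.2, n_collinear_pairs=2, n_constant=1, seed=11)
dataset = generate_dataset(spec)

table, constants = remove_constant(dataset.table)
table, collinear = collinearity_filter(table, threshold=0.9)

split = kennard_stone_split(table, n_train=35)
train = table.select_rows(split.train_indices)
test = table.select_rows(split.test_indices)

model, history = ga_select(train, GAConfig(seed=11))
print(model.equation())
s = model.fit_stats
print(f"N = {model.n_train}  R2 = {s.r2:.3f}  Q2 = {s.q2_loo:.3f}  RMScv = {s.rmscv:.3f}")

report = tropsha_check(s.q2_loo,
                       external_validate(test.activity, predict(model, test)))
print(f"R2pred = {report.r2_pred:.3f}  rm2 = {report.rm2:.3f}  "
      f"K = {report.k:.2f}  K' = {report.k_prime:.2f}  "
      f"overall {'PASS' if report.overall_pass else 'FAIL'}")

ranked = screen(model, test)
top = ranked.records[0]
print(f"h* = {ranked.h_star:.2f}; top candidate {top.candidate_id}: "
      f"predicted pIC50 = {top.predicted_activity:.2f}, "
      f"leverage = {top.leverage:.3f}, reliable = {top.reliable}")
```

Output:

```
pIC50 = 4.936 (± 0.026) − 0.691 (± 0.027) X01 + 0.933 (± 0.026) X02 + 1.089 (± 0.023) X03 − 0.501 (± 0.023) X04 + 0.742 (± 0.031) X05 − 0.142 (± 0.029) X08 + 0.088 (± 0.025) X14 + 0.066 (± 0.025) COLb2
N = 35  R2 = 0.996  Q2 = 0.992  RMScv = 0.169
R2pred = 0.947  rm2 = 0.922  K = 0.98  K' = 1.02  overall PASS
h* = 0.77; top candidate cmpd008: predicted pIC50 = 7.11, leverage = 0.295, reliable = True
```

The GA recovers all five planted descriptors (X01–X05) plus three
small-coefficient extras; the regression equation shows each coefficient
with its standard error; the external set passes every Tropsha rule, and
the eight-descriptor, 35-compound model has the warning leverage
h* = 3(8+1)/35 = 0.77. The same pipeline is available from the shell via
the `qsarscreen` command (`simulate`, `prep`, `split`, `select`,
`validate`, `yrand`, `screen`, `descriptors`).

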