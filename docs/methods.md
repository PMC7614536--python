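# Methods

## Kinetic models

**Full model (6 species, 14 rate terms).** Tracks 25(OH)D3, 1,25(OH)₂D3,
24,25(OH)₂D3, 3-epi-25(OH)D3, 3-epi-1α,25(OH)₂D3 and the catabolic enzyme
24-hydroxylase. The 1α-hydroxylation of 25(OH)D3 is Michaelis–Menten
(rate a·x/(K+x)); every other reaction is mass action; the enzyme is
induced by the active hormone (k₁₂), produced basally (p₂₄) and degraded
first-order (k₁₄), and acts bimolecularly on 25(OH)D3 (V₄) and
1,25(OH)₂D3 (V₇). Units are fixed internally at nM and days; unit
conversion (ng/mL ↔ nM via molar masses) happens only at I/O boundaries.

Two rate-term ambiguities in the source material were resolved by the mass
balances: the epimerisation of the active hormone (R10) is driven by
[1,25(OH)₂D3] — it drains that species' balance and feeds its epimer, and
the network diagram draws no arrow from 24,25(OH)₂D3 — and the epimer-loss
term R11 acts on 3-epi-1α,25(OH)₂D3, the only species it can close. A
`paper_literal_r10` flag reproduces the alternative printed form
k₁₀·[24,25(OH)₂D3] for comparison.

**Reduced model (4 species, 8 rate terms).** Assumes the enzyme level E is
constant (k₄ = V₄·E) and lumps all first-order losses of the active
hormone (enzymatic catabolism, receptor uptake, epimerisation) into
k₇ = V₇·E + k₉ + k₁₀; the loss of 3-epi-25(OH)D3 (k₈) likewise absorbs its
onward conversion. This makes the reduction *exact*: with the enzyme
clamped, the full model restricted to the shared species is identical to
the reduced model under the parameter map, a property verified on
trajectories to 10⁻⁶ relative error.

**Steady state.** The 25(OH)D3 steady state solves
s·x² + (K·s + a − P)·x − K·P = 0, s = k₃+k₄+k₅. The constant term −K·P ≤ 0
forces the root product non-positive, so exactly one non-negative root
exists for every positive parameter set. It is computed with the
cancellation-safe (Citardauq) form q = −(b + sign(b)·√(b²−4ac))/2,
x = max(q/s, c/q), which stays accurate when P ≫ a (where the naive
formula subtracts nearly equal numbers). Degenerate cases: s = 0 has a
finite steady state only when a > P (error otherwise); a = 0 factors to
x = P/s; P = 0 gives the empty system.

**Integration.** `solve_ivp` with LSODA (stiff-capable; the active hormone
turns over ~75× faster than its substrate), rtol 10⁻⁸ / atol 10⁻¹⁰ nM by
default. Negative excursions beyond 10³·atol abort; smaller ones are
clipped to zero.

## Ratio transform

α = c₁₂₅·(K+x)/x, β = epi/x, γ = c₂₄₂₅/x. On steady-state panels these are
exactly a/k₇, k₃/k₈ and k₄/k₆. β and γ are invariant under common
rescaling of all concentrations; α needs the Michaelis constant K, a
cohort-level configuration value (default surrogate 25 nM; every report
records the K used — a fitted K can be substituted freely, and a
cohort-common K is used rather than subject-specific values). Panels with
25(OH)D3 below a floor (default 0.5 nM, the assay's low quality-control
level) are flagged `below_floor` rather than producing unstable ratios;
non-positive or missing denominators flag the subject instead of dropping
the row.

## Robust regression

IRLS with Tukey's bisquare weights w(u) = (1−(u/c)²)² for |u| ≤ c, u =
residual / (1.4826·median|residual|), scale recomputed each iteration,
iterated to relative parameter change < 10⁻⁸ (max 100 iterations). The
tuning constant defaults to c = 4.685, the conventional 95%-efficiency
value at the Gaussian model. R² uses the ordinary definition on the robust
fit's fitted values. Non-pregnant controls enter the gestational axis at
week 0 (configurable); the PET group is excluded from trend fits and shown
only for reference.

Confidence bands use the M-estimation sandwich covariance for the bisquare
ψ-function with Huber's small-sample correction, and Student-t quantiles
on (Σwᵢ − 2) effective degrees of freedom. The naive route of plugging the
final weights into the weighted-least-squares covariance was measured at
~91% coverage for a nominal 95% band — downweighted residuals understate
the scale — while the sandwich form achieves 94.1% (clean Gaussian) and
94.4% (contaminated) in 500-replicate simulations.

## PCA

Each metabolite column is multiplied by 1/mean so its mean is exactly one
(metabolites span ~2.5 orders of magnitude in absolute level), rows
missing any required metabolite are removed (complete-case, counts
reported per group), then columns are centred and the sample covariance
eigendecomposed — covariance PCA, not correlation: the mean-one scaling is
the normalisation choice, and no further unit-variance scaling is applied.
Components are ordered by decreasing variance with a deterministic sign
convention (largest-magnitude loading element positive). The default
five-metabolite panel adds 25(OH)D2 as the fifth analyte; this is a
configurable assumption.

## Classification

Apparent (resubstitution) accuracy is the primary score — the fraction of
correct classifications on the fitting data — with seeded 5-fold
cross-validated accuracy reported alongside for multivariate rules, since
apparent accuracy is optimistic on small cohorts (the null calibration
below quantifies by how much).

**1-D rules** are found by exhaustive search over all midpoints between
sorted distinct values plus a rule beyond each extreme (covering majority
vote), in both orientations; ties break toward the larger margin, then the
lower threshold. This is provably the apparent-accuracy optimum among all
single-feature linear rules and is tested against brute-force enumeration.

**Multivariate rules** start from soft-margin linear SVMs (scikit-learn
SVC, linear kernel) on standardised features over the grid
C ∈ {0.01, 0.1, 1, 10, 100}. Because the hinge loss maximises margin, not
accuracy, each fitted direction has its intercept re-optimised by an
exhaustive threshold scan along the projection, and the single-feature
threshold rules compete in the same candidate pool; the apparent-accuracy
maximiser is returned (ties toward smaller C), with weights mapped back to
original concentration units. This guarantees the multivariate result is
never worse than any single-feature rule — the property a "best linear
decision function by accuracy" must have, which vanilla SVC violates (gaps
up to 0.10 and sub-majority apparent accuracy were observed on null
fixtures). Zero-variance features are dropped with a warning; rows
incomplete for the active subset are dropped per subset; classes are not
reweighted (the cohorts are near-balanced).

## Synthetic cohorts

Each subject is treated as at quasi-steady state (the analyses are
cross-sectional): subject-level rate constants are drawn log-normally
around group means (mean-preserving parameterisation), optionally scaled
by a linear per-week gestational trend, the closed-form steady state is
computed, multiplicative log-normal measurement noise is applied per
metabolite, and entries are masked independently at random. Group effects
are planted as rate-constant fold-changes, so the generator's ground truth
is exactly recoverable through the ratio transform on noiseless data
(k₃ fold m ⇒ β fold m; k₇ fold m ⇒ α fold 1/m).

Defaults, chosen once for realism:

| quantity | default | rationale |
|---|---|---|
| half-lives | 25(OH)D3 15 d, 1,25(OH)₂D3 0.2 d, 24,25(OH)₂D3 7 d, epimer 15 d | literature-scale turnover |
| reference NP3 panel | 50 / 0.15 / 4.0 / 2.5 nM | healthy third-trimester serum levels |
| K | 25 nM (surrogate) | sub-saturating at typical 25(OH)D3 |
| between-subject CV | P₂₅ 0.5; rate constants 0.2 | vitamin D supply varies far more across people than enzymatic rates |
| gestational trend | a +2.5%/week, P₂₅ +0.5%/week | active hormone roughly doubles by term |
| measurement σ (log) | 0.08 | assay RSD ~5–10% |
| missingness | 0.05 per metabolite | ≈24% of five-metabolite panels incomplete |
| floor | 0.01 nM | below quantification ⇒ missing |
| cohort sizes | 20/25/21/22 (cross-sectional), 25/25 (15-week) | realistic study power |
| PET effect | k₃ ×2.0 (term), ×1.2 (15-week) | upregulated epimerisation, milder early |

What the generator does *not* emulate: correlated (shared-extraction)
measurement error, informative missingness, demographic covariates, BMI or
seasonal structure, and any within-subject longitudinal dynamics. Passing
tests therefore show the pipeline recovers the structure it assumes — not
that real sera satisfy those assumptions.

## Calibration results computed by the test suite

On null cohorts (no planted effect, n = 100+100, 100 seeds) every
classifier's mean apparent accuracy falls in [0.55, 0.59] — comfortably
inside the [0.50, 0.62] optimism band, quantifying resubstitution bias.
With a planted k₃ fold-change of 2.0 at measurement σ = 0.25 and n =
20+20, the β-only classifier averages 0.815 apparent accuracy against
0.746 for the best single metabolite, and the best ratio subset beats the
best single metabolite in ~88% of seeds. The *strict per-seed* dominance
of β alone over every single metabolite occurs in ~77% of seeds: the
epimer concentration itself inherits the planted k₃ effect (it is the
best single metabolite in nearly every remaining seed) while β carries
doubled measurement noise, so strict dominance in ≳90% of small-cohort
draws would require implausibly large between-subject 25(OH)D3 spread
(log-SD ≳ 1). The comparison is reported as measured.

## Problem sizes

Simulation sizes in the tests and acceptance script — 100 parameter draws
for steady-state/ratio properties, 100 seeds × 200 subjects for null
calibration, 100 seeds × 40 subjects for effect detection, 500 replicates
for band coverage, 200 fixtures for classifier enumeration — were chosen
so each property estimate's Monte-Carlo error is small against its
assertion margin while the whole suite stays interactive.

## Known limitations

* The surrogate parameter set reproduces a reference panel by
  construction; it is a documented stand-in, not a fit to patient data.
* α depends on K, which cannot be identified from a single cross-sectional
  panel; it must be supplied.
* Apparent accuracy is optimistic; the CV estimates in the reports are the
  better guide to generalisation and are systematically lower.
* The steady-state assumption ignores acute supplementation dynamics.
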