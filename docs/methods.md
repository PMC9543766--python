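# Methods

## Model and dual solver

The package fits ε-insensitive support vector regression: find the
flattest function `f(x) = Σ θᵢ K(xᵢ, x) + b` that deviates from each
target by at most ε, with violations penalized linearly at rate C (only
the linear ε-insensitive loss is implemented). The primal is solved
through its dual,

maximize  Σ yᵢθᵢ − ε Σ(αᵢ + αᵢ*) − ½ θᵀ K θ
subject to Σθᵢ = 0, 0 ≤ αᵢ, αᵢ* ≤ C,  θᵢ = αᵢ* − αᵢ,

a concave box-and-equality-constrained QP whenever K is positive
semidefinite. The solver is sequential minimal optimization on the
2n-variable (α*, α) formulation with maximal-violating-pair working-set
selection; convergence is declared when the KKT gap m(β) − M(β) (the
spread of feasible bias values, in target units) falls below `kkt_tol`
(default 1e−3 UPDRS points; the oracle-comparison tests run at 1e−8).
The iteration cap is 1e5·n. No shrinking or kernel approximation is used,
so the solution matches a generic QP solver to tolerance; tests verify
dual-objective agreement within 1e−6 against an SLSQP oracle on random
problems.

Numerical choices:

- **Bias.** The prediction includes b (recovered from KKT conditions, not
  part of the dual). With free support vectors (0 < |θᵢ| < C), b is the
  mean of their tube-boundary values; with none, the midpoint of the
  interval that bound and interior points jointly allow. A degenerate
  all-zero solution (e.g. constant targets) therefore yields b at the
  midpoint of the feasible interval. An empty interval beyond tolerance
  raises an error rather than guessing.
- **Minimal-norm decomposition.** After convergence, min(αᵢ, αᵢ*) is
  subtracted from both so αᵢ·αᵢ* = 0 exactly; θ and the objective are
  unchanged.
- **Support set.** |θᵢ| > 1e−8·C. Predictions use support rows only.
- **ε = 0** is allowed (the tuning grid includes it); the tube degenerates
  and most points become support vectors, which is expected.
- **Gram caching.** The full Gram matrix is precomputed up to 1e4 rows.
- **Admissibility guard.** Kernels flagged inadmissible are refused before
  solving; negative curvature along a working pair (a non-PSD Gram beyond
  round-off) raises an admissibility error during iteration.
- Working-set ties break to the lowest index, so runs are bitwise
  reproducible; the solver-config seed exists for interface stability but
  changes nothing.

## Kernels

RBF `exp(−γ‖x−z‖²)` (γ > 0), polynomial `(1 + σ⟨x,z⟩)ᵖ` (σ > 0, integer
p ≥ 1), their convex sum (weight β ∈ (0,1) on the RBF term) and their
elementwise product, plus a plain inner-product kernel (`linear_raw`) kept
for hand-solvable fixtures and nonnegative scaling of any kernel. All are
Mercer kernels; admissibility is checked empirically as the minimum
eigenvalue of the symmetric Gram being ≥ −tol·n (tol = 1e−8, scaled with n
to absorb eigenvalue round-off; duplicate rows merely make the Gram
rank-deficient, which is fine). A positive-exponent RBF variant
(`literal_rbf`) exists only to demonstrate, in tests, that the unbounded
form fails the PSD check — it is refused by the solver.

**Kernel scale defaults.** On z-scored features, ⟨x,x⟩ ≈ d, so both shape
parameters default to 1/d: γ = 1/d (the common SVM default) and σ = 1/d.
The latter matters: with σ = 1 and d = 18 the polynomial factor's diagonal
is (1+d)² ≈ 361 against off-diagonal entries of order one, which turns
both mixtures into memorizing interpolators (zero training error, poor
generalization). σ = 1/d is the same normalization scikit-learn applies to
its polynomial kernel. Both parameters, and the degree (default p = 2, as
used in the grouped analysis), are exposed in the tuning grid.

## Tuning protocol

Grids default to ε ∈ {0, 0.1, …, 1.0} and C ∈ {2², …, 2⁹} (88
combinations); β ∈ {0.1, …, 0.9} for the sum mixture. Selection minimizes
validation RMSE, with ties broken toward smaller C and then smaller ε
(flatter, sparser models). The selection metric had to be chosen; RMSE is
consistent with the reported headline metric. There is no cross-validation:
an 8 % patient-proportional tuning subset is held out, split once (seeded)
into a 2/3 fit piece and a 1/3 validation piece, and the winning
hyperparameters are refit on the 72 % training partition. The tuning
subset never contributes to reported train/test metrics. In the per-group
analysis, a group whose tuning subset has fewer than 8 recordings selects
hyperparameters on its tune+train rows instead (the test partition is
untouched); groups too small to split at all are skipped with a warning.

## Data handling

The canonical schema is the UCI telemonitoring table (subject#, age, sex
with 0 = male / 1 = female as in the UCI file, test_time, motor/total
UPDRS, 16 voice measures). Splits are patient-proportional: within each
patient, label counts follow largest-remainder rounding of the (tune,
train, test) fractions with ties and degenerate cases resolved in the
priority train > test > tune, and assignments are permuted by seed. A
uniform tuning-subset mode is available since a uniformly drawn tuning
subset is equally plausible; the default is patient-proportional
throughout. Grouping is gender × age with the threshold at 65 years; age
exactly 65 goes to the older group (the boundary had to be placed
somewhere). Feature sets: `pooled` (16 voice + age + sex), `voice_only`
(grouped analysis), or custom columns; test_time is excluded by default
(it is a reference axis, not a predictor) but available via custom sets.
Standardization is z-scoring with statistics fitted on training rows only.

## Synthetic cohort generator

The generator emulates the telemonitoring study design so the entire
pipeline is testable offline: ~42 patients (28 men / 14 women by default),
ages uniform on 36–85, roughly weekly sessions over 180 days with several
recordings per session (~140 per patient), UPDRS assessed at anchor visits
(days 0 / 90 / 180) and linearly interpolated to recording times, total
UPDRS clipped to [7, 55], motor UPDRS an affine transform of total plus
noise (schema fidelity only — no claims attach to it).

Structure, per patient:

- A latent severity score that drifts linearly over the trial
  (rate ~ N(0.5, 0.3) severity-SDs per trial, centered at mid-trial so
  cohort-level moments stay at their targets). The progression shows in
  the voice features *and* in the UPDRS anchors — without this coupling,
  within-trial UPDRS change would be unpredictable from voice and
  trajectory tracking would be impossible.
- Per-patient idiosyncratic offsets for each feature block (anatomy and
  habit), giving the high between-patient ICC seen in repeated voice
  recordings; the cohort is a set of well-separated patient clusters,
  which is why subject-preserving splits matter.
- Session-level day-to-day variation shared by all recordings of a
  session, plus small per-recording measurement noise (SD 0.15 on the
  z-scale): same-session recordings are near-replicates, as in the real
  data.
- Correlation targets: 0.9 within the jitter (5 features) and shimmer
  (6 features) blocks and −0.6 between HNR and NHR, with latent loadings
  analytically compensated for the attenuation induced by the lognormal
  marginals so the targets hold on the observed scale.
- Marginals are moment-matched (lognormal for the skewed strictly-positive
  measures, Gaussian otherwise) to the published cohort summary; only
  mean and SD are matched — real marginal shapes are not otherwise known.

The ground-truth UPDRS function is
`baseline + 0.35·(age−65) + 4·[male] + 8·tanh(1.5·z_PPE) +
6·tanh(−1.5·z_HNR) + 2·z_DFA + 5·tanh(1.5·z_PPE)·tanh(−1.5·z_HNR)`,
clipped to [7, 55], with z-scores on the cohort moments. The saturating
and interaction terms make the feature→UPDRS relationship genuinely
nonlinear over the realized feature range (scales chosen so the nonlinear
block is comparable to the demographic trend); zeroing them leaves an
exactly affine function for tests. Anchor values are the ground truth of
the patient's *expected* profile at each visit plus N(0, 1.5) visit noise;
recording-level targets add N(0, 2) measurement/interpolation noise.

What the generator does **not** emulate: acoustic signal processing (it
produces the feature table directly), non-Gaussian patient-effect
distributions, medication or diurnal effects, missingness, and the exact
marginal shapes of the real features. Tests passing on synthetic cohorts
therefore validate the machinery and the qualitative structure
(collinearity, patient clustering, interpolated labels, nonlinear
response), not performance on the real cohort.

## Metrics and reporting

MAE, RMSE, and two R² variants side by side: the variation ratio
Σ(ŷᵢ−ȳ)²/Σ(yᵢ−ȳ)² (headline; nonnegative, exceeds 1 for over-dispersed
predictions — a documented pathology) and the conventional 1 − RSS/TSS
(cross-check). Gain percentages are 100·(ref − value)/ref for error
metrics and 100·(value − ref)/ref for R²; group averages are unweighted
means across groups. Trajectory reports list a subject's recordings in
time order with actual values, in-sample fits (training rows) and
out-of-sample predictions (test rows).

## Problem sizes

The test suite and the acceptance script use scaled-down cohorts chosen to
exercise every pathway at interactive speeds: 20 patients × ~30 recordings
(~600 rows, ~430 training) for the kernel-ordering experiments over 10
seeds; 200 random configurations (n ≤ 50, d ≤ 8) for the Mercer checks; 50
random problems (n ≤ 20) for solver-vs-QP-oracle agreement; smaller
cohorts (6–16 patients) for workflow tests.

## Known limitations

- Exact solving is O(n²)–O(n³); the full UCI table (4223 training rows)
  fits, but larger cohorts need subsampling — no low-rank approximation is
  provided by design.
- On synthetic cohorts at the scaled-down size, the product mixture
  consistently beats an affine least-squares baseline, but its margin over
  a tuned radial-only SVR is within seed-to-seed noise (the acceptance
  experiment reports both win counts); separating the two reliably needs
  larger cohorts or stronger global structure than the generator's
  defaults produce.
- The variation-ratio R² rewards dispersion, not accuracy; rank models by
  RMSE/MAE and use the conventional R² as the sanity check.
- The tuning protocol deliberately avoids cross-validation; with small
  tuning subsets the selected hyperparameters are noisy, which is visible
  in grid-search score tables.
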