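# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Connectivity model and preprocessing

Subject data are timepoints × nodes ROI time series on a fixed 19-node
salience-network atlas (7 anterior, 12 posterior nodes; 17 carry MNI
coordinates). Cleaning is a single OLS residualization against the
intercept, a centered linear trend, and any supplied nuisance regressors,
followed by a zero-phase (forward–backward) 4th-order Butterworth
low-pass at 0.1 Hz. Projecting trend and nuisance jointly — rather than
sequentially — makes the detrend/regression step an orthogonal projection
and therefore exactly idempotent; the filter stage is not exactly
idempotent (its passband gain is below unity near the cutoff), which is
inherent to any IIR low-pass. Rank-deficient nuisance matrices are
reduced to a linearly independent column subset with a warning.

Connectivity is the Pearson correlation of cleaned node pairs,
Fisher-z transformed after clipping r to ±(1 − 1e−7) so degenerate
perfectly-correlated pairs stay finite (z ≈ 8.4). Matrices are stored
with an exactly symmetric array and a zero diagonal on both scales, so
binary-mask algebra (elementwise multiplication) is well defined.

Framewise displacement uses the Power formulation with a 50 mm head
radius: rotations (radians) are converted to arc length and summed with
absolute translation increments. The radius and the formulation are
exposed as parameters.

## Network-based statistic

Edge statistics are pooled-variance two-sample t values over subjects'
Fisher-z edges. The primary threshold (default 3.1) is strict
("exceeding"), applied one-sided in the patient < control direction by
default (two-sided optional). Clusters are connected components of the
supra-threshold graph and are sized by **edge count** — chosen because
reported edge tables enumerate edges, and it is the common NBS default.
The permutation null permutes group labels, recomputes steps 1–3, and
records the maximal component size; component
p = (1 + b)/(N + 1), never zero. When the number of distinct label
assignments C(S, n1) is at most min(10^5, requested permutations) the
null is enumerated exactly; otherwise assignments are sampled uniformly
(with replacement, standard NBS practice). The permutation engine is
vectorized over permutations (a single indicator-matrix product yields
all edge t values), which is what keeps the calibration simulations in
the test suite cheap: 200 null cohorts × 500 permutations run in seconds.

## Classification

Features are the masked-edge z values; labels are +1 (patient) / −1
(control). Each LOOCV fold standardizes features by the training fold's
mean/SD (LIBSVM-era practice varies; the flag `standardize=False`
disables it) and fits a soft-margin linear SVM with cost C = 1 by
default (no value is standard; exposed as a parameter). Metrics come
from pooled held-out predictions; AUC from pooled decision values (a
single AUC over folds). Permutation p-values re-run the *entire* LOOCV
per label shuffle with the (1 + b)/(N + 1) estimator; undefined null
metrics (zero-denominator ratios) never count as exceedances.

Discriminative weight = mean of |w| across folds (mean signed w is also
stored, since reported tables print signed values while ranking uses the
absolute mean); the selection threshold is the mean + 1 sample SD
(n − 1) of that column, with strict inequality, so a degenerate
all-equal column selects nothing. The top-fraction rule keeps
max(1, ⌊fraction·count⌋) edges sorted by statistic, ties broken by edge
identifier.

Balanced-label LOOCV carries a small pessimistic bias under label
permutation (removing a subject tilts the training set toward the
opposite class); with strong cluster structure and shuffled labels the
mean null accuracy can sit visibly below 50%. The permutation test is
unaffected because observed and null runs share the estimator.

## Association

Method choice is per pair: Pearson iff both variables pass Shapiro–Wilk
at α = 0.05 (the screening test is a choice; the convention it mirrors
names no test), Spearman otherwise, computed on average ranks.
Normality is screened in the patient group only, matching the analysis
population. No correction is applied to the headline p-values
(faithful to common reporting practice), but Benjamini–Hochberg
q-values are always emitted alongside, with a configurable flagging
threshold (default p < 0.01).

## Mediation

Three OLS fits on complete cases (complete-case deletion is logged)
share the covariate set (age, 0/1 gender, education). The decomposition
c = c′ + a·b is an algebraic identity of OLS on a common sample and is
asserted to 1e−10 on every fit. The indirect-effect CI is a percentile
bootstrap over subjects (BCa is deliberately not the default, matching
the most common convention for this model); resampling is
seed-deterministic and vectorized (batched normal equations), with
rank-deficient resamples redrawn under a bounded retry budget.

Effect taxonomy: no effect (CI covers 0); suppression (CI excludes 0,
total and direct both non-significant at α = 0.05); full mediation (CI
excludes 0, total significant, direct not); partial mediation
otherwise.

**Calibration caveat.** Under the double null (a = b = 0) the
percentile-bootstrap test of a·b is structurally conservative: the CI
excludes zero only when both path estimates sit ~2 SE from zero
simultaneously, so the rejection rate is on the order of α², not α
(measured here: 1/500 at nominal 5%). Coverage of the true value is
therefore ≥ nominal — the CI never under-covers, which the suite
asserts — but a near-nominal 5% double-null rejection rate is not a
property this method has. Under single-path nulls the rate approaches
nominal.

## Synthetic cohort generator

The generator defines the study conditions the suite measures against:
43 subjects per group by default, 19 nodes, 230 retained volumes at
TR = 2 s, a 24:19 male:female split, demographic/clinical/behavioral
marginals taken from the bundled reference tables (e.g. hemoglobin
89.7 ± 22.3 g/L in patients).

Time series are zero-mean Gaussian with a block-structured correlation
matrix (within-subnetwork r = 0.30, between r = 0.15) — downstream
stages consume only second-order structure, so no hemodynamic model is
simulated. Patient-group deficits subtract delta_z from chosen edges on
the Fisher-z scale; the resulting matrix is repaired to positive
definite by eigenvalue clipping (floor 1e−6) and the generator refuses
configurations whose repair would move any entry by more than 0.05,
since those deficits are not jointly achievable by any correlation
matrix.

The mediation structure sets one edge's latent z per subject to
i_M + a·X + e_M (X is the standardized clinical variable; a, b, c′
default to 0.5/0.4/0.1 with e_M SD 0.3 and e_Y SD 1.2) and produces the
outcome score from the Y equation. Two safeguards keep the per-subject
matrix valid: the two mediator-edge nodes are coupled to the rest of the
network at only r = 0.10, giving the edge a wide admissible range, and
the latent z is clipped at |z| ≤ 1.8 with any residual repair applied
before the *achieved* edge z is used in the Y equation — so the
structural model remains exactly self-consistent with what the
connectivity matrix contains. Coefficients are on the standardized-X
scale; `mediation_table(standardize_x=True)` returns the fitting frame
on that scale.

Motion traces are six-parameter Gaussian random walks (translation step
0.04 mm, rotation step 6e−4 rad per frame), giving mean FD around
0.17 mm, in the range of well-behaved adult cohorts.

**What the generator does not emulate.** Between-subject variance in
connectivity is sampling noise only (except at the mediator edge), so
planted deficits of delta_z = 0.5 are far easier to detect and classify
than real group differences of similar mean size — which is why the
end-to-end demonstration reaches 100% LOOCV accuracy where a real cohort
reached ~72%. Passing calibration tests show the *inference machinery*
is valid (type-I control, permutation exactness, estimator identities),
not that real-data effect sizes would be recovered. Scanner artifacts,
physiological noise, autocorrelated BOLD spectra and site effects are
out of scope.

## Problem sizes used by the test suite

Simulation-based checks use: 200 null cohorts (20/group) × 500
permutations for NBS type-I error; 50 replicates (40/group) for
planted-deficit recovery; 500 replicate cohorts (n = 100) × 1000
resamples for bootstrap null calibration; n = 200 for mediation path
recovery. The acceptance script uses 100 null cohorts, 30 power
replicates, one 43-vs-43 end-to-end run (1000 NBS permutations, 200
classifier permutations) and 5000 bootstrap resamples.

## Pipeline reproducibility

Every stage seed derives from hash(global seed, stage name), so adding a
stage never perturbs earlier stages' randomness, and rerunning a
configuration reproduces all stochastic outputs exactly. All artifacts
are plain text (TSV/JSON/YAML) and re-loadable by the package's own
readers, which validate symmetry, finiteness (naming offending cells)
and atlas label agreement.
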