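# Methods

This note documents the statistical models behind `floramorph`, the
assumptions they make, the defaults and why, and the numerical choices that
matter. It is written for a user who wants to know exactly what each number
means — not just which function produced it.

## Data model

A dataset is `n` specimens × `p` landmarks × 3 coordinates with specimen /
species / group labels and a missingness mask (`LandmarkTable`). Landmarks
are homologous points; labels are 1-based integers. The built-in flower
scheme has `p = 37`: 1–10 stamen appendage tips, 11–20 appendage bases,
21–30 anther pores, 31 style base, 32 stigma, 33–37 petal tips. A
`ModuleHypothesis` assigns every landmark to exactly one named module; the
five built-in hypotheses partition the flower developmentally (H1, four
organ whorls) or functionally (H2–H5, attraction / efficiency /
reproduction variants with 2–3 modules). Which stamens form androecium
whorl 1 in H1 is not encoded by the landmark scheme and is a user
parameter (default: stamens 1–5).

Trees are rooted, dated (ultrametric) phylogenies with tip labels matching
species ids. Ultrametricity is checked with relative tolerance 1e-6 on the
root-to-tip depth spread; violations warn rather than fail, because Newick
round-trips drift in the last digits.

## Generalized Procrustes alignment

Each configuration is centred and scaled to unit centroid size, then
iteratively rotated onto the running consensus by proper orthogonal
Procrustes (SVD with a determinant correction — biological configurations
must never be mirrored). The consensus is the mean of aligned
configurations; iteration stops when the summed squared change of the
consensus falls below 1e-10 (at most 100 iterations). Scaling is not
re-adjusted after rotation (partial Procrustes), so centroid size is the
size variable removed from shape. Consequence worth knowing: the partial
Procrustes consensus coincides with the full-Procrustes mean only in the
small-dispersion limit (differences ~3e-8 at within-sample noise sd 0.01
on unit-size shapes, growing quadratically); the tests verify the
consensus against a direct minimization of the partial-Procrustes
objective, plus agreement with a full-Procrustes fixed point at low
dispersion.

PCA of the flattened `3p` coordinates uses the covariance
eigendecomposition with no tangent-space projection; at the dispersions of
aligned landmark data the difference is far below the other noise sources,
and keeping the raw linear space makes reconstruction exact.

PROTEST compares two matched 2D ordinations: both are centred and scaled
to unit total sum of squares, the statistic is `t = sqrt(1 − m²)` after
optimal orthogonal superimposition (reflection allowed, as is conventional
for ordination comparison), and `p = (1 + #{t_perm ≥ t_obs})/(nperm + 1)`
over row permutations.

## Missing-landmark estimation

Damaged specimens (1–10 unplaceable landmarks in the motivating data) are
completed from a reference set of complete specimens — by default the
complete conspecifics when at least two exist (four for regression),
otherwise all complete specimens.

* **TPS**: the Procrustes mean of the reference set is similarity-aligned
  to the damaged specimen on the shared landmarks; a 3D thin-plate spline
  (biharmonic kernel `U(r) = r` plus a full affine term, solved as one
  linear system; condition number above 1e14 is an error) maps the aligned
  reference shared landmarks onto the specimen's, and the reference's
  missing positions are pushed through the warp. TPS interpolates the
  shared landmarks exactly and reproduces affine relations exactly.
* **MS**: the aligned reference mean's positions fill the gap.
* **REG**: per missing landmark, least squares of its coordinates on the
  shared-landmark coordinates across reference specimens. Reference sets
  are far smaller than the `3p` predictors, so predictors are reduced to
  the first `min(n_ref − 1, 10)` principal components.

Validation removes `k ~ U{1..kmax}` random landmarks from a random intact
specimen, re-estimates, and scores (i) per-landmark displacement in units
of the specimen's centroid size and (ii) PROTEST concordance of the
first two PC axes of the estimated vs intact alignments; per-landmark
Welch-T and two-tailed F tests compare dispersion around the consensus.
Welch's form is used because the two sets have different dispersions by
construction. The observer-error test applies the same machinery to
replicate digitizations vs independent specimens; a usable landmarking
scheme shows replicate errors an order of magnitude smaller.

## Covariance-ratio modularity

For modules A and B with covariance blocks `S_AB` of the flattened
coordinates,

```
CR(A,B) = sqrt( tr(S_AB S_AB') / sqrt( tr(S_AA* S_AA*') tr(S_BB* S_BB*') ) )
```

with more than two modules the overall CR is the mean over module pairs.
`S*` excludes the **whole 3×3 within-landmark block**, not just the
variable diagonal: a landmark's own coordinate (co)variances are not trait
covariation, and only the block-level exclusion keeps CR invariant under
rotations of the coordinate frame (every retained term is then the
Frobenius norm of a between-landmark block). Two facts users should not
trip over:

* CR is *not* exactly 1 for exchangeable data at finite module size: with
  all between-landmark cells equal, `CR = sqrt(q_A q_B / sqrt(q_A(q_A−1)
  q_B(q_B−1))) > 1` because a pair of modules has `q_A q_B` between-cells
  but only `q(q−1)` within-cells. The permutation null absorbs this
  counting asymmetry; the raw CR value alone does not.
* Each module needs at least two landmarks, or its within denominator is
  empty.

The permutation null reassigns whole landmarks (each carrying its three
coordinates) to modules of the observed sizes; the observed assignment
counts as one permutation, so `p = #{CR_perm ≤ CR_obs}/nperm` has floor
`1/nperm` (0.001 at the default `nperm = 1000`). The effect size
`z = (mean(perm) − CR_obs)/sd(perm)` is signed so that larger positive
values mean stronger modularity.

**Comparing strength between groups.** Each `z` is a standard deviate of
its own permutation null; under the hypothesis of equal modularity
strength the difference is approximately normal, and the two-sample
statistic is `z_12 = (z_1 − z_2)/sqrt(se_1² + se_2²)` with unit standard
errors by default (a permutation standard deviate has unit sampling sd
under the null; this is what makes the comparison calibrated — verified by
a uniform-p experiment over identical-structure groups). A 10-block
split-sample estimator of the Monte-Carlo error of each `z` is available
as a diagnostic (`se="blocks"`); it measures permutation noise (~0.1 at
nperm=1000), not sampling variability, and must not be used as the test's
standard error. When both groups are strongly modular the unit-se test is
mildly conservative (the sampling sd of a far-tail standard deviate drops
below 1).

**Phylogenetic variant.** For species means `Y` on a tree with Brownian
covariance `C` (entries = shared root-path length), the GLS root is
`â = (1'C⁻¹1)⁻¹1'C⁻¹Y` and the evolutionary covariance
`S_evol = (Y−1â)'C⁻¹(Y−1â)/(n−1)` replaces the sample covariance; the
landmark permutation null is unchanged. On a star tree this reduces
exactly to the ordinary test. `C` is inverted directly; condition numbers
above 1e12 trigger a warned diagonal jitter of `1e-8 · mean(diag)`.

Per-group tests are run on jointly Procrustes-fitted coordinates with
per-group centring (each group's own mean defines its covariance).

## Congruence matrices and model selection

The vector congruence coefficient between landmarks i and j is the
cosine-type correlation of their deviation vector fields across specimens,
`Σ_s d_si·d_sj / sqrt(Σ_s|d_si|² Σ_s|d_sj|²)`, with deviations taken from
the per-dataset consensus. Note this is a *signed dot product*: unlike
CR, it is sensitive to the relative orientations of landmark deviations,
not only to their magnitudes.

Candidate models pool the `p(p−1)/2` upper-triangle cells into parameter
classes via the grammar {single within-module ρ | one per module} ×
{single between-module ρ | one per module pair}; coincident partitions are
deduplicated (for two modules the between variants coincide) and a
single-ρ null is appended — 15 models for the five flower hypotheses.
Each cell's Fisher z is modelled as normal around its class mean with
variance `1/(N−3)` (`N` = specimens behind the matrix, carried inside the
`CorrelationMatrix` so it cannot desynchronize); the class MLE is the mean
z, back-transformed per class. `K` counts only the ρ parameters — the z
variance is fixed, not estimated — and
`AICc = −2logL + 2K + 2K(K+1)/(n_r − K − 1)` with `n_r = p(p−1)/2`.
Correlations are clamped to ±(1 − 1e-9) before `atanh`; negative
congruences are legitimate and kept.

## Phylogenetic signal, rates, ancestral states

`K_mult` is the multivariate phylogenetic-signal ratio
`[tr(D'D)/tr(D'C⁻¹D)] / [(tr(C) − n/(1'C⁻¹1))/(n−1)]` with `D = Y − 1â`;
it is ≈1 under Brownian motion, scale-invariant in the branch lengths, and
tested by shuffling tip rows (`p = #{K ≥ K_obs}/(nperm+1)`, observed
included). On noisy species means (few specimens per species) K sits
below 1 even for Brownian evolution — within-species noise is
non-phylogenetic variance.

Per-module net rates whiten the means by the Cholesky factor of `C`
(`Z = L⁻¹(Y − 1â)`), estimate per-dimension rates `σ²_j = Σ_i Z_ij²/n`,
and average over each module's `3 p_m` dimensions. The max/min ratio `R`
is tested by simulation under a common-rate null that **preserves the
observed among-trait correlation**: each module's whitened residuals are
rescaled to the pooled rate and rows are resampled through `L`. Simulating
independent coordinates instead is sharply anti-conservative on correlated
shape data (type-I error ~40% at α=0.05 in our calibration experiments vs
~6% with the correlation-preserving null).

Discrete ancestral states use Mk likelihoods (matrix exponentials, pruning
algorithm, flat root prior), with one rate (ER) or `k(k−1)` rates (ARD)
optimized by Nelder–Mead on log rates; marginal node probabilities come
from combining downward partial likelihoods with an upward outside pass.
AIC compares ER vs ARD. A requested state list may include states not
observed at the tips (needed for degenerate datasets); it must cover all
observed states.

Continuous trait models (on PC scores) profile the mean and `σ²` by GLS
and optimize the remaining parameter by bounded 1-D search, additionally
evaluating the bounds themselves (the bounded optimizer never quite
reaches them): λ ∈ [0,1] scaling off-diagonal `C`; OU with the
ultrametric fixed-root covariance
`V_ij = σ²/(2α) e^{−2α(T − s_ij)}(1 − e^{−2α s_ij})` and α ∈ [1e-6, 50/T];
Early-Burst with `(e^{a s_ij} − 1)/a`, a ∈ [−10/T, 0]. AICc uses k = 2
(BM) or 3 parameters. Non-ultrametric trees are an error for OU/EB rather
than a silent stationarity assumption.

## Regime-shift search

Shifts in phenotypic optima are modelled as a multi-optimum OU with global
α and σ²: a shift on branch b moves the optimum for b and everything below
it, so tip expectations are linear in the regime optima with weights
`e^{−α(T − t_end)} − e^{−α(T − t_start)}` along each root path (the root
state is pinned at the root optimum). Optima are profiled by GLS; α by
bounded search.

Selection is greedy forward search over all branches. The criterion is a
BIC with a multiplicity correction: `log n` per optimum **plus `2 log m`
per shift for its estimated location** (m = number of candidate branches).
Plain BIC is not usable here — the best of ~60 candidate branches on
shift-free Brownian data routinely gains more log-likelihood than
`log(n)/2`, so uncorrected greedy selection accepts spurious shifts almost
always; the location charge restores specificity (≥90% of Brownian nulls
select zero shifts) while 5-sd optimum shifts on identifiable branches are
still localized in >80% of runs. For speed, each round scans candidates
at a small grid of probe α values (a single incumbent α can zero out
internal-branch design columns when it is extreme) with one covariance
factorization per probe, then refits the best three candidates with α
free. After selection, pairs of regime optima are merged whenever the
criterion drops; merged regimes on disjoint clades are reported as
convergent. The selected configuration's criterion never exceeds the
zero-shift model's, by construction.

Identifiability caveats users should expect: a shift on a branch arising
near the present moves its tips only a fraction `1 − e^{−α(T−t_start)}` of
the optimum displacement and may be undetectable at any sensible size; and
a shift on one child of the root is equivalently parametrized on the other
child, so "localization" includes the sister branch.

## Synthetic data generator

The generator is the ground truth for every test. Defaults emulate the
motivating study design: 37 landmarks under the 3-module functional
partition, 30 species in 3 groups on a unit-depth pure-birth (Yule) tree,
specimen counts uniform on 1–8 per species (~4 on average, ~137 total),
random specimen pose/scale (rotation uniform over proper rotations,
translation in a unit box, scale log-uniform in [0.5, 2]), and ~47% of
specimens damaged with 1–10 missing landmarks. Group regimes are painted
on the tree by clade (preferring mid-sized clades so no group is left with
one or two species); species means evolve by Brownian motion with
per-module rates (or OU with group-specific optima), and specimens deviate
from their species mean with sd 0.05 per coordinate — roughly 1% of the
base-shape centroid size, small against the between-species signal, chosen
for test power (the motivating data publish no within-species covariance
estimates). The base shape is a deterministic Fibonacci sphere with
per-module offsets, guaranteeing non-degenerate 3D geometry.

Covariance structure is landmark-level block correlation: all coordinates
of same-module landmarks correlate at `rho_w` (default 0.7), across
modules at `rho_b` (default 0.1), at both the specimen level and in the
evolutionary increments (so modularity is detectable both within groups
and across species). The generator has **two regimes**:

* `scatter_directions=True` (default): the correlated draw is expressed in
  a fixed random rotation frame per landmark (deterministic from the
  seed). This leaves the block structure exactly intact at the
  landmark-block level — CR sees only Frobenius norms of 3×3 blocks, which
  are invariant to per-landmark rotations — while making modules *deform*
  coherently rather than translate. This matters: with unscattered
  compound-symmetric correlation the module common factor is a
  near-uniform module translation, and Procrustes centring converts that
  into between-module anti-correlation (in a worked 10-landmark example
  the CR of the centred covariance flips from 0.16 to 1.37), silencing the
  signal after GPA. Real shape variation deforms; so does this regime.
* `scatter_directions=False`: correlations live on the raw coordinates.
  This is the "synthetic block matrix" regime: the vector congruence
  coefficient (a signed dot product, not frame-invariant) then carries the
  block structure, and coordinate-level covariance recovery can be checked
  directly. Congruence-based model selection is validated in this regime.

What the generator does **not** emulate: measurement error with spatial
autocorrelation along organ surfaces, allometry (shape–size covariation),
bilateral symmetry constraints, and within-species phylogeographic
structure. Passing tests therefore demonstrate correctness and calibration
of the estimators under a controlled modular model, not that any
particular empirical dataset is modular.

## Robustness harnesses

Rarefaction draws one specimen per species (singletons are forced picks),
down-sampling keeps `max(min_per_group, ceil(fraction·n_g))` species per
group (default fraction 0.5, floor 4) and one specimen each; each
replicate re-runs GPA and the requested analyses from scratch (never
slicing the full-data alignment), with per-rep seeds drawn from one seeded
generator so runs are exactly reproducible. Summaries report mean CR / p /
z and the proportion of replicates significant at α = 0.05 per hypothesis
and group, best-model counts, fastest-module counts, and per-species
shift-inclusion proportions. Resampled datasets keep a canonical species
order so that identical draws produce bitwise-identical analyses.

## Problem sizes in the test suite

The statistical tests run at sizes chosen to finish in minutes while
keeping the Monte-Carlo error far from the asserted margins: permutation
tests use 200 permutations inside calibration loops (500 null datasets for
type-I error; 200 datasets for power and comparison calibration), rate
recovery uses 100 trees of 100 tips with 99 null simulations each, OU
recovery 100 fits on 100-tip trees, and shift detection 200 searches on
32-tip trees. The exactness checks (GPA invariance at 1e-8, TPS
interpolation at 1e-8, round-trips at 1e-12, enumeration of the CR null on
6 landmarks) are not size-limited.

## Known limitations

* The congruence/model-selection path assumes landmark deviation fields
  with consistent orientations (see the two generator regimes above); on
  strongly reoriented data it loses power by design of the statistic.
* The greedy shift search is myopic: two same-optimum shifts inside one
  larger clade may be fitted as a single ancestral shift, and shifts that
  jointly inflate the apparent phylogenetic variance can depress the
  single-shift gain below the acceptance threshold.
* Effect-size comparisons use unit standard errors; for strongly modular
  groups this is mildly conservative.
* GPA convergence to 1e-10 in the consensus leaves ~1e-6-level
  order-dependence in downstream statistics; resampled analyses therefore
  fix the specimen order.
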