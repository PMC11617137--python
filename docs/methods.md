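# Methods

## Task design

Eight trial types cross hand (H), target (T) and gaze (E) side (left/right).
Near/far levels are derived, not free: a pair is *near* exactly when its two
elements share a side.  Board geometry is parameterized by the three LED
separations (hand 2.3 cm, target 6.9 cm, gaze 32.9 cm, collinear and
symmetric about the center), from which all pairwise distances follow as
|±sep_a/2 ∓ sep_b/2| — e.g. gaze-target 13.0 cm (same side) / 19.9 cm
(opposite), hand-target 2.3 / 4.6 cm, hand-gaze 15.3 / 17.6 cm.

A run is 40 trials, exactly 5 per type.  Delay durations {1, 2, 4, 8, 16} s
and plan durations {4, 6, 8} s are assigned by largest-remainder rounding of
the stated proportions ([0.52, 0.26, 0.13, 0.06, 0.03] and
[0.56, 0.30, 0.14]) to exact per-run counts ({21, 10, 5, 3, 1} and
{22, 12, 6}); remainder ties go to the rarer level first, then the shorter
duration.  Go/no-go is exact-count, not Bernoulli: 3 go + 2 no-go per trial
type (24/16 = 60% overall), which also guarantees every condition regressor
has at least two no-go events, so no design matrix can have an empty
condition column.  Post-cue structure: no-go trials close with a 2.5 s
feedback window + 1 s gap; go trials are modeled with a nominal 1 s reach
plus a 1 s gap (movement duration is a simulation convenience, not an
estimate).

GLM design matrices model each no-go trial's planning as a 2 s boxcar — at
target onset (early epoch) or ending at the go/no-go cue (late epoch) — per
condition, plus nuisance regressors for pooled go-trial planning, go-trial
movement, and a constant.  Boxcars live on half-open [on, off) intervals at a
0.05 s microtime grid, are convolved with a canonical double-gamma HRF
(gamma(6,1) response minus gamma(16,1)/6 undershoot; impulse response peaks
~5 s), and sampled at TR = 0.45 s with 0-based scan indexing.  A 20 s tail
pads each run so the last responses return to baseline.

The VIF of a design is the mean over task regressors (the 8 condition columns
and the go-planning column) of `inv(A)[i,i] * A[i,i]` for the task-column
Gram matrix A — the variance inflation of each weight relative to estimating
it alone; 1 iff the columns are orthogonal.  `optimize_design` draws
candidate runs on spawned child streams of one seed (so candidate k is
identical whatever the total candidate count — the achieved VIF is
non-increasing in the search size) and keeps the candidate whose *worse*
epoch VIF is smallest, so a single run serves both epoch GLMs.  With this
trial composition random candidates score ≈1.005, comfortably under the 1.15
acceptance bound; the optimizer mainly guards against unlucky orderings.
Whether nuisance movement regressors should enter the VIF set is not
determinable from the design description; we use the estimated-weights-of-
interest set and expose the full matrix for alternatives.

## Components and the generative model

Direction contrasts are the side codes (left = −1, right = +1) of T, H, E;
distance contrasts are elementwise products of two side codes (+1 = near).
Model matrices G_c = c cᵀ / 8 are rank-1, PSD, trace-normalized (so fitted
weights are comparable across components) with equal diagonals.  The six
contrasts are distinct main effects / two-way interactions of the 2³
factorial; with the all-ones vector and the three-way product they form a
complete Hadamard basis, hence the G_c are pairwise trace-orthogonal and
every model covariance is simultaneously diagonalizable.  The outer product
cancels a global left/right sign flip, so the numeric coding convention is
immaterial.

Synthetic voxels are i.i.d. zero-mean Gaussian 8-vectors with covariance
Σ = Σ_c w_c G_c + σ² I — exactly the covariance family the fit assumes.  The
generator emulates the statistical structure of condition-wise GLM betas, not
fMRI physics: no spatial smoothness, drift, or autocorrelation, and condition
patterns are redrawn independently per run (so run-averaging over R runs
scales the whole covariance by 1/R).  Passing tests therefore demonstrate
correctness of the estimator under its own assumptions, not robustness to
real-scanner artifacts.  Between-subject weight heterogeneity is available as
lognormal jitter (off by default).  Optional BOLD simulation composes the
generative design matrix (both epochs' condition regressors as truth) with
white noise, for end-to-end GLM tests; estimation is plain OLS with an
explicit rank check (robust reweighting would have nothing to do on white
noise).  Standard fixtures: `tiny` = 4 subjects × 2 runs × 200 voxels
(seconds to fit), `paper_scale` = 27 × 6 × 2000.  The tiny fixture's default
planting (w_ET = w_T = 0.5, σ² = 1) is a moderate regime — detectable in
aggregate but deliberately not a give-away; tests that need near-certain
single-dataset detection plant w = 4.

## Fitting, free energy, and component evidence

U is mean-centered across conditions by default (the shared mean is not among
the modeled components).  Centered 8-vectors live in the 7-dimensional
subspace orthogonal to the ones vector, so the likelihood is evaluated there:
S and every G_c are projected through an orthonormal basis of that subspace
(all contrasts are orthogonal to ones, so no component energy is lost) and
the noise term stays the identity.  This handles the rank-deficient centered
covariance exactly instead of ridging it.

Fisher scoring maximizes the penalized log-likelihood of the log-scale
weights h with step-halving (Σ(h) is positive definite for every finite h, so
only non-ascent triggers halving); tolerance 1e−4 on the objective change,
max 128 iterations, h clipped to ±40.  Initialization is moment-matching —
h_m = log of the projection trace(Q_m S)/trace(Q_m Q_m), floored at 0.1% of
the mean data variance — because the log-scale gradient vanishes as
exp(h) → 0 and a start in that corner would be a fixed point.  The free
energy is the Laplace evidence F = L(ĥ) − ½(ĥ−η)ᵀΠ(ĥ−η) + ½log|Π| +
½log|C|, with posterior covariance C from the Fisher-plus-prior curvature.
Fits are batched: shuffle tests run all (permutation × subject × reduced
model) problems through one vectorized Fisher-scoring loop with per-item
convergence.

Hyperpriors are Gaussian on h with mean −32 and variance 256 — components
are "off" a priori, with a prior broad enough that a few dozen voxels of
signal switch one on.  Putting the prior mean at the same value used to pin a
component during model reduction is essential: it makes the posterior of an
unsupported component collapse onto the pin, so removing it costs ≈0 nats.
(With a data-scale prior mean such as −3, removing even an irrelevant
component is charged the prior-to-pin quadratic — thousands of nats — which
contradicts the intended "irrelevant components cost nothing" semantics.)

Component evidence is ΔF = F_reduced − F_full with the component's prior
pinned at mean −32, variance 1e−6; more negative = stronger contribution.
Two routes are implemented:

* **refit** (default): re-optimize the reduced model, warm-started from the
  full posterior mode with the pinned coordinate moved.  The pinned
  coordinate is excluded from the Newton step so its enormous prior gradient
  cannot distort the free coordinates.
* **bmr**: the analytic Gaussian model-reduction identity on the full
  posterior.  It agrees with the refit when a component's posterior sits on
  the pin, but for any materially positive fitted weight it extrapolates the
  quadratic posterior across the long flat tail of the likelihood
  (exp(h) → 0 saturates L, a Gaussian in h does not) and overstates |ΔF| by
  orders of magnitude.  It is retained because the identity is the classical
  formulation; its scale inflation is harmless to shuffle-null inference,
  which only compares evidences across relabelings, but the refit values are
  the interpretable ones and all reports use them.

Group evidence is fixed-effects: log evidences add over independent
subjects.  A random-effects alternative is out of scope.

## Shuffle null and credibility

K permutations of the 8 condition labels (drawn with replacement from the
8!−1 non-identity permutations; one permutation per iteration, shared across
subjects to preserve group-level exchangeability) are applied to each
subject's U — equivalently, to the rows/columns of its second-moment matrix —
and the entire fit → reduction → group pipeline is rerun per permutation.
Iteration 0 is the identity, so the "real" evidence is by construction the
same code path as the null draws.  Log Bayes factors are
LBF_k = ΔF_shuffled,k − ΔF_real (positive = real labels carry more
evidence); summaries are the median and the 95% highest-density interval
(shortest interval on the empirical sample).

The credibility rule: center the shuffled evidences on their own median to
form a null LBF reference set, and flag a component at level q ∈ {0.80, 0.95}
iff median(LBF) ≥ ln 3 + quantile_q(reference).  "Three times more credible"
is the ln 3 margin on the log-evidence scale; a degenerate (constant) null
reduces the rule to median(LBF) ≥ ln 3.  Under label-exchangeable data the
real statistic is exchangeable with the shuffled ones, so the ln 3 margin
makes the criterion conservative: measured false-positive rates at the 95%
level are far below nominal (0/200 per component in the acceptance run), and
detection of a planted component rises monotonically with its variance
(0/10 → 9/10 → 10/10 → 10/10 at w = 0.5, 1, 2, 4 on the tiny scale).

## Problem sizes in the test suite

Unit tests run at 200–10,000 voxels, single subjects, and K ≤ 100; the
acceptance suite uses 200 pure-noise tiny datasets and 25 datasets per power
point at K = 200, and 200 design candidates for the VIF search.  These sizes
were chosen so the full suite completes in a few minutes on one core while
keeping Monte-Carlo error well inside every asserted margin (e.g. RMSE
consistency uses 20 replicates with nested voxel subsets as common random
numbers).

## Known limitations

* OLS replaces robust-WLS volume down-weighting; irrelevant for white-noise
  simulations, a compatibility gap for real scanner data.
* Voxels are treated as exchangeable given Σ (no spatial covariance), both in
  the generator and the likelihood.
* The direction components are interpretationally confounded (absolute vs
  relative position) by design of the factorial; the package makes no attempt
  to disambiguate them.
* Whether to include a shared-mean component instead of centering is exposed
  via `center=False` but not otherwise modeled.
* The Gaussian BMR identity's scale inflation for supported components (see
  above) means its raw values should not be read as refit-equivalent log
  evidences.
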