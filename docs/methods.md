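# Methods

## Channel model and estimation

Within one analysis window of length `n` samples, the directed interaction
from sender `x` to receiver `y` is modelled as a linear time-invariant FIR
channel with additive white Gaussian noise,
`y_t = sum_j a_j x_{t-j} + w_t`, `a_j >= 0`, `w_t ~ N(0, sigma^2)`
independent of `x`.  The nonnegativity constraint restricts the model
class to positive couplings (negative couplings are hard to interpret in
global-signal-regressed data); the all-zero coefficient vector is the
legitimate "no positive channel" answer, not an error, and maps to zero
capacity.

The receiver vector and each lagged sender column are standardized by
removing the mean and dividing by the root mean square with the
**population divisor n**.  This choice makes the unit sender-power
constraint of the capacity problem exact and gives the order-1 fit a
closed form: `a_0 = max(r, 0)` and `sigma^2 = 1 - a_0 (2r - a_0)`, with
`r` the sample correlation of the standardized signals.  Under the
Gaussian likelihood the constrained MLE is the NNLS solution
(`scipy.optimize.nnls`, a deterministic convex program) and the noise MLE
is the mean squared residual — hence `0 <= sigma^2 <= 1` always.

**Lag boundary handling.**  The lagged design matrix needs `k - 1`
samples before the window.  By default they are taken from the recording
immediately preceding the window ("lookback") when available; otherwise
the first `k - 1` rows are truncated so only fully observed lag vectors
are regressed.  No data is ever fabricated; both behaviours are exposed
through `allow_truncation` / `use_lookback` flags.

**Order selection.**  Candidate memories `k = 1..k_max` are scored with
Gaussian-likelihood information criteria: `AIC = n ln sigma^2 + 2k`,
`BIC = n ln sigma^2 + k ln n`, `AICc = AIC + 2k(k+1)/(n-k-1)`, where `k`
counts the FIR taps (the noise variance is omitted identically across
candidates, leaving rankings unchanged).  Ties break toward the smaller
order.  The default cap is `k_max = min(8, n // 10)`, which keeps the
regression strongly overdetermined; note that for 16-sample trial blocks
this resolves to 1, i.e. trial-level fits are memoryless by default.
AICc is the recommended criterion for such short single-window trials,
BIC for sliding windows of 50+ samples.

## Capacity estimation

The equivalent input noise PSD is `S_EIN(f) = sigma^2 / |H(f)|^2`, with
`H` the DTFT of the tap vector, approximated by an FFT of the taps
zero-padded to grid size `N` (default 4096, a power of two; the
grid-refinement study shows relative changes < 1e-3 when doubling N for
orders <= 8, so the default is safely converged).  Capacity is the
discrete water-filling solution: the EIN values are sorted ascending,
candidate levels `lambda_m = (N + sum_{l<m} S^(l)) / m` are computed, the
active count is the largest `m` with `lambda_m > S^(m)` (the admissible
set is a prefix, so this is the index of the first failure), and
`C = (2N)^{-1} sum_{l<m} log(lambda_m / S^(l))`.  The discrete power
budget `(1/N) sum_active (lambda - S) = 1` holds exactly by construction
and is asserted at run time.

Numerical edge handling:

- bins where `|H(f)|^2` is below `1e-15` of its maximum (e.g. the exact
  spectral zeros of symmetric tap vectors) are treated as zero-response:
  infinite EIN, never active;
- finite EIN values above `1e12` are likewise excluded — their capacity
  contribution is below machine precision, while their magnitude breaks
  float arithmetic in the water level;
- a perfectly noiseless fit (`sigma^2 = 0`) yields infinite capacity,
  which is the correct limit and propagates as `inf` rather than raising;
- the budget assertion tolerance scales with the magnitude of the active
  bins, since the identity can only hold to the relative precision of its
  summands.

Capacities are in **nats** at the library level, so closed-form test
identities read without conversion factors; the CLI defaults to bits and
every output file carries a units column.  Mixing units across files in
one validation run is refused.

## Sliding-window framework

Windows are the maximal equally spaced set fully contained in the series:
`M = floor((T - n)/step) + 1`.  Window lengths given in seconds are
converted through the TR and floored with a warning for non-integer
division.  Per window and directed pair the pipeline yields capacity,
prediction-correlation (`corr(y, X a)`, 0 for the all-zero fit), SWC
(Pearson correlation of the raw segments) and duration (`k` in TRs); a
degenerate (constant) window produces NaN in **all four** series at that
index, keeping cross-modal window pairing aligned.  The estimation path
contains no randomness, so reruns are bit-identical.  A single window
spanning a whole short trial reproduces trial-level analysis.

For 16-sample trial batches with the default memory cap (which resolves
to 1) the batched trial path evaluates the closed-form order-1 fit
vectorized; the test suite asserts agreement with the generic per-window
pipeline to float precision.

## Validation procedures

**Sensitivity.**  Per directed pair, units (subjects) contribute one
task and one rest value (their trial means).  Pairs with between-unit
coefficient of variation of the task value >= 30% (or nonpositive mean,
where CV is undefined) are excluded; the remainder get right-tailed
paired t-tests (task > rest) and Benjamini–Hochberg correction across
tested pairs with q < 0.02.  The CV filter is what controls false
positives in practice: null pairs have near-zero mean capacity and
CV far above the threshold.

**Specificity.**  Per scan, the directional asymmetry of a pair is
`|mean_fwd - mean_bwd|` of the time-averaged connectivity; the reference
scan-to-scan variability is the standard deviation across scans of the
mean of the two directions (the symmetric choice).  H0: median asymmetry
>= variability, tested with a left-tailed Wilcoxon signed-rank test at
alpha = 2%; rejecting H0 means the measure shows *less* directional
asymmetry than its own scan-to-scan fluctuation — the desired behaviour
on resting data with no expected hemispheric bias.  Zero differences are
dropped (Wilcoxon's original rule; if all differences are zero the test
returns p = 1, i.e. no evidence).  The exact null distribution is used
for small samples without ties.

**Cross-modal correspondence.**  Windowed series are compared by
bootstrap over windows (resampled with replacement within scan, identical
indices in both modalities, concatenated across scans before the Pearson
correlation); time-averaged matrices by bootstrap over scans.  Summaries
are the replicate mean, percentile CI and the one-sided p-value for a
positive correlation (fraction of replicates <= 0).  All resampling is
driven by a seeded NumPy Generator.

**States.**  Window-resolved directed matrices are vectorized over
off-diagonal entries and pooled; k-means (Lloyd, Euclidean, 6 seeded
initializations per k, best WCSS kept) is run for k = 1..10.  Features
are used unscaled: capacity is already on a common scale across pairs.
The elbow is the maximum second difference of the WCSS curve after
normalizing both axes to [0, 1], ties toward smaller k; if the whole
curve drops by less than 20% there is no cluster structure and k = 1 is
returned (the second-difference rule alone cannot reach the endpoint).
Cross-modal state labels are aligned by exhaustive search over the k!
centroid pairings maximizing total Pearson correlation (guarded at
k <= 8).  State labels are 0-based.

## Synthetic data: what it emulates, and what it does not

The generators produce data satisfying exactly the assumptions the
estimator makes — white (optionally AR(1) or band-limited) Gaussian
senders, nonnegative FIR coupling, independent additive Gaussian noise —
so parameter-recovery and detection studies are well posed:

- **Coupled pair**: direct forward model of the channel.
- **Bilateral null** (22 scans by default): a shared latent drive
  filtered by identical taps (0.7, 0.7) into both ROIs plus independent
  unit noise; a per-scan gain ~ U(0.7, 1.3) creates scan-to-scan
  variability.  Directions are exchangeable by construction.
- **Directed alternative**: one-way coupling with taps (0.5, 0.5) and
  the same gain jitter.  Memory >= 2 matters: at order 1 the
  standardized fit is symmetric in its arguments, so one-tap coupling
  cannot produce directional asymmetry in any estimator of this family.
- **Task/rest**: 30 subjects x 20 pairs x 4 trials of 16 samples per
  condition; the 4 planted pairs carry order-1 coupling with tap 1.0
  (task SNR 1) in task trials only.
- **State sessions**: window features drawn around planted centroids,
  with the minimum centroid separation fixed at 10x the expected
  within-state deviation norm, plus a schedule-driven multi-ROI
  time-series generator for end-to-end runs.

Real recordings violate these assumptions in known ways: hemodynamic
convolution and band-limiting color both signal and noise, coupling is
not time-invariant within windows, noise is neither white nor Gaussian,
and multivariate confounds make pairwise channels an approximation.
Passing the synthetic studies therefore shows the estimator and tests are
*correct under the model class*, not that the model class captures any
particular dataset.

## Study sizes used by the tests and acceptance script

All studies run at desk scale, chosen so each completes in seconds to a
few minutes on one CPU: specificity uses 22 scans of 360 samples with
60-sample windows, step 5, BIC with k_max 3 and grid N = 512, for 100
replicates per hypothesis; sensitivity uses the full 30-subject design
for 200 planted seeds and 1000 all-null seeds (vectorized trial path);
parameter recovery uses 100 seeds; state recovery 20 seeds of 2000
windows.  Full-scale settings (e.g. 1000-volume scans, 100-sample windows at
step 1, N = 4096) run through the same code path, proportionally
slower.

## Known limitations

- Pairwise channels only; no conditional/multivariate formulation, so
  common drive can appear as reciprocal capacity.
- Linear FIR with Gaussian noise; nonlinearity, feedback and
  non-Gaussian noise are outside the model class.
- The elbow rule is a deterministic stand-in for a visual judgement and
  is validated only on planted-state simulations.
- Capacity is reported per sample (per TR); comparisons across
  modalities with different TRs should convert to per-second rates.
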