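# Methods

This note documents the generative model behind the synthetic sessions, the
analysis conventions, the numerical choices inside the classifiers, and the
limits of what the test suite can demonstrate.

## Generative model of a session

Each subject's session is a set of stimulus-locked epochs
(trials × channels × samples, μV).  Trial *t* with emotion *e* on channel
*c* is

    x_tc(τ) = w_c · A_t · exp(−(τ − (μ + δ_t))² / (2σ²)) + ε_tc(τ)

- **Component.** A Gaussian-envelope, negative-going deflection peaking at
  μ = 170 ms with envelope SD σ = 25 ms.  σ was set so that the default
  10 ms latency jitter attenuates the grand-average peak by only ~7%,
  keeping the average an honest image of the single-trial template.
- **Amplitude.** A_t = a(e) · exp(N(−s²/2, s²)) with s = 0.2 — a unit-mean
  lognormal multiplier, so single trials vary but condition averages stay
  at their nominal amplitude.  Nominal amplitudes: positive trials
  a = −6 μV, negative trials a = −6 − Δ μV, neutral halfway between.
- **Latency jitter.** δ_t ~ N(0, 10 ms): the main reason single-trial
  classification is harder than comparing averages.
- **Topography.** w_c ∈ [0, 1] is a fixed unitless gain per channel,
  maximal at P7/P8 (1.0) and PO7/PO8 (0.95), falling toward midline sites,
  zero at Fz.  The default montage is the 12 occipitotemporal candidates
  plus six context channels.
- **Noise.** ε is Gaussian noise shaped to a 1/f^α spectrum (α = 1) in the
  frequency domain, rescaled to SD 2 μV per channel, independent across
  trials and channels.
- **Artifacts.** With probability `artifact_rate` a trial receives a brief
  ±180 μV transient on one channel and is flagged, so the ±100 μV rejection
  stage can be cross-checked against the injection exactly.
- **Behavior.** Reaction times are Gaussian per emotion (negative 600 ms,
  positive 650 ms, neutral 655 ms; SD 80 ms, truncated at 1 ms) and
  accuracy is Bernoulli (0.96 / 0.92 / 0.93), reproducing a
  negative-emotion speed and accuracy advantage.

### Choosing the effect size

No published amplitude difference in μV was available to anchor Δ, so it is
a free parameter calibrated once and then frozen.  The calibration target
is the regime in which the analysis is scientifically interesting: a Bayes
accuracy of ≈ 0.85 for the positive/negative decision from one trial —
comparable to the per-subject accuracies such experiments report.  Measured
as large-sample Fisher-discriminant accuracy on the 65-dimensional feature
vector (a consistent estimate of the Bayes rate for these near-Gaussian
classes), Δ = 5 μV with 2 μV noise gives ≈ 0.856.  Notably, the jitter
terms — not the additive noise — dominate the error floor: with the default
amplitudes, no noise level reaches Bayes 0.85 at Δ ≤ 4 μV.

### What the generator does not emulate

Spatially *correlated* noise (volume conduction), non-stationary drift,
ocular/myogenic artifact waveforms, overlapping components (e.g. the P1 or
the vertex positive potential), or realistic head-model projection.
Passing tests therefore demonstrate that the pipeline recovers structure
from data with the assumed statistics, not that it would achieve these
numbers on recorded EEG; in particular, independent channel noise makes
multi-channel averaging more profitable than it is in practice.

## Preprocessing conventions

- Operation order is configurable; the default is re-reference → baseline →
  rejection → band-pass.  Each operation is pure and carries trial IDs so
  label/data alignment is verifiable.
- Re-referencing is a generic linear operator M·v per sample vector
  (average reference: M = I − 11ᵀ/n).  Computing an infinity-reference
  (REST-style) matrix from head-model lead fields is out of scope; such a
  matrix can be supplied.
- Baseline window is half-open [−200, 0) ms: the sample at stimulus onset
  belongs to the post-stimulus segment.
- Rejection removes trials with any |sample| **strictly** above 100 μV
  ("±100 μV" read as the allowed range), after baseline correction, on all
  channels.
- Band-pass is a 4th-order Butterworth applied forward–backward
  (zero-phase, so peak latencies do not shift) with odd-reflection padding
  of one epoch length.  On 480 ms epochs the 0.5 Hz high-pass corner
  necessarily leaves slow transients; the filter tests therefore measure
  gain on long signals away from the edges.

## Statistical conventions

- All t tests are two-sided; p-values come from the regularized incomplete
  beta function.  Trial-level positive-vs-negative contrasts use Welch's
  two-sample t (trials are not naturally paired); a trial-order-paired
  variant exists for group-style maps, labeled as such.
- The RT filter drops incorrect responses, then (per emotion, per subject)
  RTs outside mean ± 2 SD computed on the correct trials; bounds are
  inclusive, SD uses n−1, and the filter is a single pass — a second pass
  can remove more rows, and a test pins this non-idempotence.
- The repeated-measures one-way ANOVA uses the subject × condition
  interaction as its error term, df = (k−1, (k−1)(n−1)), no sphericity
  correction.

## Feature construction

Channel ranking orders the 12 candidates by ascending contrast p-value
(ties broken by montage order) and keeps the top k = 5.  Default features
are the raw window samples (150–200 ms inclusive at sample resolution → 13
samples × 5 channels = 65), matching the idea that the single-trial
waveform segment — not one scalar — is the feature; a `window_mean` mode
provides the one-amplitude-per-channel alternative.  Min-max scaling bounds
are fitted per feature and stored; rows outside the fitting subset may fall
outside [0, 1] by design.

By default, channel selection and scaling bounds are re-fitted inside each
training fold (no information from test trials).  A `paper_mode` flag
instead performs the per-subject global procedure — selection and scaling on
all trials before cross-validation — which is how such analyses are often
described but lets test trials influence the feature definition; both paths
are first-class and labeled in the output.

## Classifier numerics

- **LDA.** Closed form w = S_reg⁻¹(m₊ − m₋), threshold at the projected
  midpoint.  S_reg = (1−s)·S_w + s·(tr S_w/p)·I with s either fixed or a
  Ledoit–Wolf-style estimate (default): with 65 features and ~288 training
  trials the raw scatter is ill-conditioned.  s = 0 raises on singularity.
- **L1LR.** Monotone FISTA: gradient step on the smooth average logistic
  loss (step 1/L, L = ‖[1 X]‖₂²/4n), soft-thresholding prox for λ‖w‖₁
  (intercept unpenalized), acceleration with acceptance only when the
  objective does not increase — the recorded trace is non-increasing by
  construction.  Stops at relative objective change ≤ 1e−8 or 10 000
  iterations.  Before iterating, the intercept-only candidate
  v* = log(n₊/n₋), w = 0 is tested against the KKT condition
  max_j |∇_j loss| ≤ λ and returned exactly when it certifies optimality —
  this makes "w = 0 exactly at λ ≥ λ_max" an identity rather than a limit.
- **SVM.** Dual coordinate optimization over maximal-violating pairs
  (working-set size 2, analytic update, gradient maintained incrementally);
  stops when the KKT violation gap ≤ 1e−3 (tightened in oracle tests).
  Bias from free support vectors, falling back to the violation midpoint.
  Non-convergence raises, carrying the final gap.
- **Hyperparameters.** The reference analysis did not report λ, C or γ.
  `hyper="search"` runs an inner 5-fold grid search (λ over 20 log-spaced
  points in [1e−4·λ_max, λ_max]; C ∈ {0.1, 1, 10, 100} ×
  γ ∈ {0.01, 0.1, 1, 10}/p).  The documented fixed defaults
  (λ = 0.01·λ_max; C = 10, γ = 1/(p·Var(X))) are used by the simulation
  studies below so their runtime stays in seconds; the search path is
  exercised separately on a small instance.

## Evaluation conventions

Stratified 10-fold plans (class ratio per fold within one trial),
deterministic per seed; a training fold missing a class is an error.
Headline metrics are computed on the pooled test-fold predictions — AUC on
16-trial folds is too unstable to average — and the fold-averaged variants
are reported alongside (`pooling=pooled|foldmean`).  CT (summed train+test
wall time) is reported but never asserted: it is hardware-bound.  Ranking
uses α = 0.05 two-sided; classifiers whose paired difference is not
significant share a rank, and the overall winner has the most first-rank
finishes.  Score orientation is "larger = more positive-class" for all
three models; positive-emotion trials are the +1 class throughout.

## Problem sizes in the test and acceptance suites

Simulation-backed checks use: channel-set recovery, 100 seeds at 160
trials/emotion (planted 5-channel effect, Δ = 8 μV); null calibration, 120–
200 seeds at 30 trials/emotion for p-value uniformity and 5 seeds at the
full design for chance-level CA; effect-size monotonicity, 4 levels × 20
seeds at 60 trials/emotion with LDA; operating band, 3 seeds × 3 classifiers
at the full design.  The acceptance script evaluates 5 synthetic subjects ×
3 classifiers at the full 480-trial design.  These sizes keep the whole
suite in a few minutes while leaving the stochastic assertions comfortably
powered.

## Known limitations

- The SMO implementation is exact but plain Python/NumPy; for n ≫ 10³
  trials a working-set cache would be needed.
- `paper_mode` reproduces a leakage-prone procedure by design; its numbers
  should not be compared against the fold-local default.
- The behavioral generator draws RT and accuracy independently of the EEG;
  no single-trial brain–behavior coupling is modeled.
- EDF import is not implemented; external recordings must be converted to
  the documented epoch container (raw float64 + JSON sidecar).
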