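# Methods

This note documents the models, numerical choices and limitations behind
`edapain`. It is written for a reader who wants to know *what* the package
computes and *why* each open design point was resolved the way it was.

## The signal and the indices

Electrodermal activity (EDA) is skin conductance in microsiemens, driven by
sympathetic sudomotor nerve activity. A brief painful stimulus elicits a
skin-conductance response (SCR): a fast rise (~0.7 s time constant) and slow
decay (~2 s) riding on a slowly drifting tonic level. The package computes
three indices on a uniform 2 Hz preprocessed series `x(t)`:

* **TVSymp** — the instantaneous amplitude (Hilbert analytic envelope) of the
  unit-variance sum of VFCDM components 2 and 3, i.e. of the ~0.08–0.24 Hz
  band where stimulus-locked sympathetic dynamics concentrate.
* **MTVSymp** — `max(a_t − μ_t, 0)` where `μ_t` is the trailing 5-s mean of
  TVSymp. The subtraction suppresses slowly varying sympathetic tone and
  passes abrupt surges; 5 s keeps the detector near-real-time. During the
  first 5 s, `μ_t` is the mean of all samples seen so far (the definition
  needs a full window; growing the window from available history is the only
  convention that is causal and defined from the second sample; the first
  output is forced to 0).
* **dPhEDA** — the five-point-stencil derivative of the cvxEDA phasic
  component, `(x[n−2] − 8x[n−1] + 8x[n+1] − x[n+2]) / (12/Fs)` with Fs=2 Hz,
  exact for polynomials through degree 4. Ends are replicate-padded by two
  samples so the output aligns with the input; padded-edge values are
  first-order approximations only.

## Preprocessing

Raw wearable data is irregularly sampled (~15–130 Hz). The chain is: natural
cubic spline onto a 4 Hz grid anchored at the first timestamp (no
extrapolation) → centered running median, 5 samples (1.25 s; "one second" at
4 Hz is 4 samples, an even number, so the nearest odd window with ≥1 s
support is 5) → decimation to 2 Hz → 2nd-order Butterworth high-pass at
0.01 Hz, applied forward–backward in batch mode so SCR timing is not skewed
by filter phase. Streaming mode replaces only the high-pass with a causal
single pass (initialized to step state to avoid a start-up transient); the
spline and the centered median are computed incrementally with a ~1.5 s
finalization lag, which preserves batch-identical values while remaining
causal with respect to emission time.

## VFCDM

Variable frequency complex demodulation decomposes `x(t)` into 12 components
with centers 0.04–0.92 Hz in 0.08 Hz steps. Stage one demodulates at each
fixed center and low-passes; stage two estimates each band's
instantaneous-frequency track from the unwrapped phase derivative (central
differences; where the envelope is numerically zero the derivative is set to
0), smooths it, clips it to the band's span, and re-demodulates along the
track.

Numerical choices, each forced by a measurable failure of the obvious
alternative:

* **Prototype filter.** A 65-tap linear-phase FIR whose frequency response is
  a raised cosine (`cos²`) with zero gain beyond the 0.08 Hz band spacing and
  −6 dB at half the spacing, applied once as a centered convolution with
  reflected ends (zero phase, no delay). Shifted copies of a `cos²` response
  sum to exactly one, so the stage-one filterbank is a partition of unity:
  stage-one reconstruction error on band-limited signals is ~0.3% RMS. A
  Hamming windowed-sinc of the same length gave 6.3%, and applying any
  filter forward–backward squares its response, which puts a ~50% power dip
  at every band boundary.
* **Stage two operates on the stage-one band signal**, not the raw input.
  Re-demodulating the raw signal lets a neighboring band's frequency track
  migrate toward a strong off-band oscillation and recapture it at full
  gain (a pure 0.12 Hz tone then left only 64% of variance in its own
  component; band-limiting the stage-two input raises this to 99%).
* **Stage-two low-pass at twice the band width.** Its only job is rejecting
  the double-frequency demodulation image; using the narrow stage-one width
  re-attenuates in-band content relative to the moving track (15–18%
  reconstruction error vs 8%).
* **Residual correction.** The small stage-two loss is recovered by passing
  `x − Σ components` through the stage-one filterbank once and adding each
  band's share back to its component: reconstruction error drops to ~0.4%
  while band concentration stays ≥95%.
* The first band (center 0.04 Hz) keeps the DC-adjacent content; it is
  computed for completeness and never used by TVSymp. Component edges within
  ~10 s of either end are filter warm-up and flagged as untrusted.

TVSymp's unit-variance normalization divides the summed components by their
sample standard deviation without removing the mean (band-pass components
are already zero-mean). Batch mode normalizes per recording; streaming mode
cannot see the whole recording and uses a causal running estimate (below).

## cvxEDA

The tonic/phasic split solves

```
minimize  ½‖y − Mq − Bℓ − Cd‖² + α·1ᵀ(Aq) + ½γ‖ℓ‖²   s.t.  Aq ≥ 0
```

where `M`, `A` are the banded ARMA operators of the bilinear-discretized
Bateman system (`τ0`=2.0 s, `τ1`=0.7 s), `B` a cubic B-spline tonic basis
with 10-s knots, `C` offset+drift, `α`=8·10⁻⁴, `γ`=10⁻², all canonical
defaults of the convex EDA decomposition literature. The driver `p = Aq` is
the sudomotor nerve activity; the l1 penalty on the nonnegative driver makes
it sparse and burst-like.

Two solver paths give the same optimum (cross-checked to 10⁻⁶):

* **Dense exact path (≤400 samples):** the free tonic variables are
  eliminated in closed form; the reduced nonnegative quadratic is solved
  exactly by Lawson–Hanson NNLS, with the linear l1 term absorbed into the
  right-hand side (if `A = LᵀF` and `Aᵀu = α1`, then NNLS on `b − u` has the
  reduced problem's KKT conditions). Milliseconds per window; used by the
  streaming scheme.
* **Matrix-free path (longer series):** L-BFGS-B on the driver
  parametrization with analytic gradients; every operator product is an
  O(n) banded solve. Tolerance 10⁻⁸, iteration cap 20 000.

Because the input is the high-passed (signed) series, the tonic part simply
absorbs the residual low-frequency content; "tonic" here is not an absolute
conductance level. Exact scale covariance does not hold — the l1 weight is
absolute, so halving/doubling the input changes the phasic norm by ~±13%
while the phasic *shape* stays essentially identical (correlation >0.99).
This is a property of the model, not of the solvers, and the tests assert it
as such.

## Streaming scheme

Per 0.5-s hop the scheme takes a trailing window (55 s for TVSymp/MTVSymp,
25 s for dPhEDA), left-pads with the running mean while the recording is
younger than the window, right-pads 5 s with the last value (the padding
absorbs the filter edge transients), computes the index over the padded
window, and emits the mean of the final 2 s of real data. Emissions carry
both the newest sample's timestamp and the wall-clock time at which they
became available; truncating the input never changes already-emitted values.

Two window-level choices matter:

* The windowed TVSymp amplitude is taken from the VFCDM complex envelopes
  (`|Σ 2·zlp·e^{jΦ}|` over bands 2–3) rather than an FFT Hilbert transform:
  the discrete Hilbert transform is circular and its wraparound corrupts
  exactly the window end being read. Normalization uses a running
  (causal, cumulative) standard deviation of the band sum, probed 5 s inside
  the window where the estimate is reliable; it converges to the batch
  per-recording normalization.
* An emitted value is an estimate of the *recent past*, not the present: the
  2-s tail average centers 1 s back, and the one-sided window edge adds
  ~1.5 s of effective group delay. The scheme's nominal latency is therefore
  2.5 s, and comparisons against batch series align at that lag. On default
  synthetic records the streamed TVSymp tracks the batch series at Pearson
  r ≈ 0.88–0.92; the residual gap is irreducible one-sided estimation (the
  batch index at time t uses ~16 s of future data that no causal scheme can
  have).

The per-hop dPhEDA windows are decomposed with the exact NNLS path,
warm-started from the previous hop.

## Synthetic data generator

Each simulated subject is tonic + evoked SCRs + spontaneous SCRs + noise on
a jittered timestamp grid:

| parameter | default | why |
|---|---|---|
| raw rate | 120 Hz, ±20% interval jitter | wearable stream rate with radio-induced irregularity |
| stimuli per subject | 10, uniform 30–60 s apart | repeated-stimulus session design |
| SCR kernel | `e^{−t/2.0} − e^{−t/0.7}` | canonical Bateman time constants |
| evoked latency | 1.5 s | places the response inside the 5-s pain window |
| evoked amplitude | 0.5 ± 0.1 µS (floored at 0) | clear but physiological responses, 25× noise SD |
| spontaneous SCRs | 2/min, 0.05–0.3 µS | non-specific electrodermal activity |
| tonic | 2 µS + Gaussian walk, 0.01 µS/√s, floored at 0.05 µS | slow drift |
| noise | 0.02 µS white | sensor noise |

Conductance is clipped at zero and the correction folded into the stored
noise trace, so `tonic + phasic + noise` reconstructs the recording exactly.
Per-subject streams derive from `SeedSequence([seed, subject_index])`, so any
subject is reproducible in isolation.

What the generator does *not* emulate: motion artifacts, electrode drift or
detachment, nonlinear amplitude saturation, habituation across stimuli, and
responder/non-responder heterogeneity beyond amplitude jitter. Passing tests
therefore demonstrate algorithmic correctness and sensitivity under clean
conditions, not field robustness.

## Statistics

Fisher's ratio uses (n−1) variances — the conventional estimator; the
definition leaves the flavor open. AUROC is the Mann–Whitney pair-counting
probability (ties count ½, computed via midranks); its 95% CI is a
subject-stratified bootstrap (2000 resamples) because segments within a
subject are strongly correlated — resampling segments would understate the
variance. Normality is checked with a one-sample KS test against a normal
with the sample mean/SD, reported for information only. Group differences
use a subject-nested permutation rank test: mean over subjects of the
within-subject rank-sum Z (tie-corrected), with labels permuted within each
subject and a two-sided add-one p-value. A linear mixed-effects alternative
for normally distributed features is deliberately not implemented; the
permutation test is assumption-free and is applied throughout.

## Classifier evaluation

Eight families with fixed grids (SVM C ∈ {1,10,100,1000}, γ ∈ {10⁻⁴, 10⁻³,
0.1}; tree criterion ∈ {gini, entropy}; MLP 1–3×100 hidden units ×
{logistic, tanh, relu} × {sgd, adam, lbfgs} × learning rate {10⁻⁴, 10⁻³,
10⁻²}, 100-epoch cap, SGD rate divided by 5 after two non-improving epochs;
logistic-regression solver ∈ {newton-cg, lbfgs, liblinear, sag, saga};
KNN K ∈ {3,5,7,9}). Non-tree families are standardized with
training-fitted statistics only. Protocol 1 is pooled leave-one-subject-out
with a nested subject-wise 5-fold grid search (subjects shuffled by seed,
dealt round-robin); protocols 2/3 train on one dataset and test once on the
other, with a segment bootstrap CI. The MLP is scored by cross-entropy loss
(minimized), all others by accuracy; ties keep the first-listed grid point.
An audit hook lets tests verify that no fit of a fold ever sees the held-out
subject.

## Problem sizes

Default verification runs use: 300-s signals for decomposition fidelity;
one ~4.5-min subject for recovery and streaming checks; 10 subjects × 10
stimuli for end-to-end classification; 200 null datasets × 400 permutations
for test calibration; 2000 bootstrap resamples for CIs. These sizes give
stable estimates of every reported quantity while keeping a full
verification run on a single CPU in the minutes range.

## Known limitations

* All fidelity figures are for clean synthetic data (see the generator's
  non-goals above).
* The streamed index estimates the batch index at a 2.5-s lag with
  r ≈ 0.9; applications needing exact batch equivalence should recompute
  offline.
* cvxEDA hyperparameters are fixed defaults, not tuned per recording; the
  phasic norm is scale-sensitive through the l1 weight (±15% at half/double
  amplitude).
* The first VFCDM band aliases DC-adjacent content below ~0.04 Hz;
  consumers use bands 2–3 only.
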