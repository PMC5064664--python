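# Methods

`emgsketch` implements a complete recognition chain for one-stroke
sketching shapes from multichannel surface EMG (sEMG): burst segmentation,
time-domain feature extraction under two analysis-window regimes,
normalization + PCA, and a Gene Expression Programming (GEP) classifier
assembled one-against-all, with back-propagation (BPNN) and Elman (ENN)
network baselines. This note records the models, the parameter choices and
their rationale, and what the synthetic benchmark does and does not show.

## Signal model and the synthetic generator

Real recordings of this task are six-channel forearm/upper-arm sEMG
(flexor carpi radialis, extensor digitorum, extensor carpi ulnaris,
extensor carpi radialis brevis, triceps brachii, biceps brachii) sampled at
1000 Hz, paced in 3 s trials: a beep, one pen stroke of 1–2.5 s, rest.
Such recordings are not publicly available, so `emgsketch.synthetic`
generates sessions with the same structure and known ground truth:

- **Carrier.** Interference-pattern EMG is modeled as Gaussian noise
  band-limited to 10–450 Hz and normalized to unit variance. Amplitude
  features (mean, RMS, MAV) respond only to the modulation of such a
  carrier, which is exactly the information the classifier consumes.
- **Bursts.** Each trial adds one burst over a quiet baseline
  (`baseline_sd`, default 0.01; burst scale `burst_sd`, default 0.08 — a
  burst/baseline ratio of 8, comfortably above the ratio ≥ 5 at which
  0.6-RMS thresholding is well-posed). A burst is the carrier multiplied
  per channel by a class-specific gain envelope: `K = 10` piecewise-
  constant sub-segment gains spread over the burst, with 25 ms linear
  cross-fades at interior boundaries and a sharp attack at onset.
- **Class structure.** The first ~30% of every envelope is a shared attack
  phase at gain 1.5: the pen-down acceleration is a ballistic movement
  whose drive does not yet depend on the shape being drawn. The remaining
  sub-segments carry the class identity as gains `1 + separation · u`,
  `u ~ U(-1/2, 1/2)` per channel, **mean-centered per channel**: all
  shapes are drawn with the same muscles at comparable overall effort, and
  what distinguishes them is the within-stroke time course of each
  muscle's drive. Each class also receives a characteristic stroke
  duration drawn once from [1.0, 2.5] s (drawing a circle takes
  consistently longer than flicking a line), around which trials jitter by
  ±5%. Setting a profile's `duration_s=None` reverts to fully random
  per-trial durations.
- **Onset jitter.** The burst starts uniformly within
  `[0, min(0.5 s, period − duration)]` of its trial. The 0.5 s cap equals
  `trial_period − epoch_length`; it encodes prompt starts after the pacing
  beep and guarantees that a 2.5 s epoch anchored at one burst can never
  swallow the onset of the next.
- **Separation.** `separation` scales the distance between class
  envelopes. The default 1.5 was calibrated once so that the end-to-end
  benchmark with the GEP classifier lands in the ~95% accuracy regime of
  the original task; it is a configuration knob, not an empirical claim.

Two envelope choices deserve emphasis because they are *structural*, not
cosmetic. First, the detection threshold is 0.6× the whole-session RMS of
the main channel; with bursts occupying ~58% of each trial this threshold
sits at ≈ 0.46× the burst amplitude *regardless of the burst/baseline
ratio*, so exact onset recovery needs the onset phase of every burst to be
uniformly strong — the shared attack provides that margin. Second,
mean-centering the class gains means the long (2500 ms) analysis window,
which averages the whole epoch, erases most class information, while the
short (250 ms) window preserves it; the short-window advantage observed in
the benchmark therefore has a physical basis in the generator rather than
being an artifact of one random draw.

The generator does **not** model motor-unit potentials, electrode shift,
impedance drift, fatigue, crosstalk between channels, or day-to-day
variability. Passing the benchmark shows the pipeline and classifier are
correct and well-conditioned on amplitude-modulated data of realistic
geometry; it does not certify performance on human recordings.

## Segmentation

Onsets are detected on the rectified main channel (extensor digitorum by
default; RMS is rectification-invariant, the rectification is kept for
fidelity to the processing order). A 20 ms sliding window advances in 5 ms
steps; when 57 consecutive windows — spanning 300 ms — all have RMS at or
above `0.6 × RMS(whole session)`, the start sample of the first window of
the run becomes the epoch onset for all channels. Scanning resumes past
the 2.5 s epoch, so epochs never overlap (trials are 3 s apart by design).
"0.6 RMS during each set" is read as one threshold per session, computed
over the entire main-channel record — the only quantity defined at that
scope. `threshold_mult = 0` is rejected as a degenerate always-on
detector. Coordinates are 0-based samples, windows half-open, and ms
convert to samples by `round(ms · fs / 1000)`.

## Features and reduction

Per analysis window of `N` samples: `aEMG = mean(v)`,
`RMS = sqrt(mean(v²))`, `MAV = mean(|v|)`. Windows are adjacent (increment
= length): 250 ms → 10 segments × 3 features × 6 channels = 180 features
per epoch; 2500 ms → 1 × 3 × 6 = 18. Features default to the rectified
epoch (rectification precedes segmentation in the processing chain), which
makes aEMG ≡ MAV; `on_rectified=False` computes on the raw signal for
users who want a signed mean. Feature vectors are flattened in (segment,
feature, channel) order with a pandas MultiIndex.

Reduction is fitted on training data only and frozen: per-column min-max
scaling to [0.05, 0.95] (constant columns map to the 0.5 midpoint to avoid
division by zero; the value is uninformative anyway), then PCA keeping 12
components for the short window and 5 for the long. A variance-fraction
alternative (`variance_fraction=0.95`) is available but not default, since
no selection criterion is canonical here. Test data passes through the
frozen transform and may fall outside the interval.

## GEP engine

Genes are Karva strings with head `h = 15` and tail
`t = h(a_max − 1) + 1 = 16` over functions {+, −, ×, /, sin, cos, sqrt,
exp} and one terminal per principal component; chromosomes hold 3 genes
linked by addition. Fitness is `1000 / (MSE + 1)` with squared error —
the printed form of the error sum omits the square, but it is named mean
*square* error and its perfect-fit cap of 1000 requires MSE = 0, so the
squared form is implemented. Termination: fitness = 1000 (checked as
MSE == 0.0 exactly) or the generation cap.

Numerical choices:

- **Protected arithmetic.** `sqrt(|x|)`; `exp` argument clipped to
  [−50, 50]; division by `|denominator| < 1e−12` yields NaN. A chromosome
  emitting any non-finite output on any fitness case scores fitness 0 —
  penalization rather than value substitution, so the search is not biased
  toward a particular sentinel.
- **Selection.** Roulette wheel proportional to fitness with elitism of
  the single best individual, cloned unchanged into the next generation
  (best-so-far fitness is therefore monotone). An all-zero-fitness
  population falls back to uniform selection.
- **Operators and rates** (applied population-wide each generation, in
  this order): point mutation 0.044 per symbol (always to a *different*
  symbol of the position's domain), head-segment inversion 0.05, IS
  transposition 0.05 (insertion at a non-root head position), RIS
  transposition 0.05 (function-rooted transposon to the gene root), gene
  transposition 0.05, one-point and two-point recombination 0.2 each, and
  whole-gene recombination 0.05. The one-point/two-point rate is printed
  as a single figure in the source parameter table; it is read as 0.2
  *each*. Transposon lengths are drawn from {1, 2, 3}. All operators
  preserve the head/tail symbol domains, so closure is unconditional
  (fuzz-tested).
- **No random numerical constants**: the terminal set is variables only.

Binary decisions use a rounding threshold of 0.5 on the chromosome output
(`output ≥ 0.5` → positive); threshold 0 reproduces the strict sign rule.
Both conventions appear in the source method; 0.5 is the default.

## Classification

One-against-all: 11 binary problems, class j coded 1 against 0. At
prediction, exactly one firing binary wins; zero or several firings fall
back to the argmax of raw continuous outputs (non-finite ranks lowest),
keeping prediction total. Models are per-session (per-subject); no
pooling.

The BPNN is input → sigmoid hidden (25 nodes short window / 11 long) →
tanh output; the ENN adds a context layer feeding the previous sample's
hidden activations back into the hidden layer (zero initial context;
context treated as a constant input during backpropagation — truncated
gradient, the standard Elman simplification). Targets are ±0.9 to sit
inside the tanh range; batch gradient descent with learning rate 0.01 and
momentum 0.9 runs until training MSE < 0.01 or 2000 iterations. None of
these training constants are canonical (the original models were built in
a GUI tool); they are ordinary defaults and are exposed in `NNConfig`.

Splitting is stratified by class, 70% train (770/330 for the full 1100-
trial protocol), deterministic under a seed; an optional `blocks` argument
refines strata to (class, block) where day/block structure exists.
Accuracy is reported per class as `AR = c/C × 100%` and summarized as the
unweighted mean over classes (AR₁₁).

## Benchmark problem sizes

`pipeline.run_benchmark` defaults to 11 classes × 20 repetitions (220
trials, 660 s of six-channel signal), both window regimes, and a GEP
budget of 50 chromosomes × 1000 generations per binary problem — a
desk-scale setting chosen so a full run completes in about two minutes on
one core; the canonical budget (50 × 2000) is available through
`gep_generations`. In the benchmark, detected onsets are labeled by the
nearest ground-truth onset from the synthetic metadata (rather than
positionally), so a hypothetical single detector miss would cost one trial
instead of desynchronizing every subsequent label; with the default
conditions the detector recovers all 220/220 trials.

At these conditions (seed 0) the GEP classifier reaches test AR₁₁ ≈ 98.5%
with the short window and ≈ 45% with the long window; seeds 1–2 give
97–100% (short). The short-over-long ordering is asserted by the test
suite only directionally — its magnitude depends on the generator's
mean-centering choice and is larger than on real recordings, where slower
amplitude cues survive the long window.

## Known limitations

- The generator's classes differ only in amplitude-envelope time courses
  and durations; spectral or phase cues are absent by construction, and
  aEMG carries no information beyond MAV on rectified data.
- The Elman baseline treats the (shuffled) training set as a presentation
  sequence; for this static task the context layer is noise, and the ENN
  should not be expected to beat the BPNN here.
- GEP training cost scales linearly in population × generations × classes;
  the engine is vectorized over fitness cases but evolves in pure Python.
- Filters (`bandpass`, `notch`) are provided for real recordings and CLI
  use; synthetic data is generated in-band, so the benchmark skips them.
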