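# Methods

This note documents the generative model behind the synthetic experiments,
the analysis pipeline's numerical choices, and the design decisions taken
where the problem was genuinely open. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic experiment

### Stimulus design

The generator emulates a factorial scene-perception experiment: every
combination of room (20), action (6), character (3), and camera spawn point
(4) occurs exactly once, giving 1440 stimuli. Five rooms are held out of
training and shared between the test and validation sets; the four cameras
split into one pair for test and the complementary pair for validation, so
the splits are 1080 / 180 / 180 and generalization is across rooms.
Repetition counts default to 5 (train), 30 (test), and 5 (validation) per
stimulus, i.e. 5400 / 5400 / 900 trials. One presentation sequence of 10
trials at 300 ms stimulus + 100 ms intertrial interval spans 4 s.

### Annotations

Each of seven features carries one annotation per stimulus in a fixed shape
class: grayscale map (edges, lighting, scene depth), RGB map (reflectance,
world normals), a 14×2 body-joint coordinate matrix (skeleton), and a
length-6 one-hot vector (action identity). Maps default to 36×27 (the shape
*class*, not the resolution, is contractual — full-resolution 520×390 maps
would only scale the PCA). Continuous annotations are low-rank linear images
of per-stimulus latents plus small full-rank pixel noise; a shared latent
with weight ρ makes the between-feature correlation controllable. ρ defaults
to 0 (independent features): the recovery guarantees below assume separable
features, and correlated features are an experimental manipulation, not a
baseline. The action annotation is the exact one-hot encoding of the design's
action factor. Video mode repeats each annotation over 9 frames with small
i.i.d. frame jitter (σ = 0.05; one-hots stay constant), mirroring a 30 fps,
300 ms clip.

### EEG forward model

The response is an exact linear function of the annotations:
`signal(s,c,t) = Σ_f κ_f(t) · [a_f(s)ᵀ P_f W_f]_c`, with per-feature random
projections `P_f` (to a rank-5 latent) and channel mixings `W_f` drawn once
per run, channel patterns rescaled so the per-channel signal s.d. at the
kernel peak equals the feature amplitude (default 1.0). The temporal kernel
is Gaussian, `κ_f(t) = exp(−(t−τ_f)²/2σ_f²)` with σ_f = 30 ms, gated to zero
before stimulus onset so the pre-stimulus window is noise only (the ungated
tail at t < 0 would be ≤ 0.03 anyway). Trials add Gaussian noise with channel
covariance `corr(c,c′) = 0.5^|c−c′|` (unit variances), so the whitening stage
has real structure to remove. Temporal noise is white across timepoints.
Groups of subjects share the design, annotations, and planted projections and
differ only in their noise streams.

**Planted latencies.** Defaults are
edges 80, reflectance 120, lighting 160, world normals 200, scene depth 240,
skeleton 300, action 420 ms — a low → mid → high ordering consistent with the
visual-hierarchy literature. Two deliberate choices: the values are
*grid-aligned* (multiples of the 20 ms sampling step) and spaced ≥ 40 ms
(two samples). A latency placed midway between two grid points makes the
discretized argmax of a symmetric kernel a noise-broken coin flip between the
two neighbors, and with 20 ms spacing two adjacent features can then collide
into a rank tie; grid alignment plus two-sample spacing makes the rank
ordering of recovered peaks a stable property of the defaults rather than of
the noise draw. They are generator defaults, not claims about any real
recordings.

**Signal-to-noise.** With amplitude 1 against unit channel noise, encoding
accuracy at a feature's peak lands around r ≈ 0.8–0.9 — above zero and below
the split-half lower noise ceiling (≈ 0.95 at 30 test repetitions), which is
the intended regime: accuracies are informative but measurement-limited, as
the test `test_encoding_accuracy_below_lower_ceiling_in_signal_window`
verifies at the peaks.

### Layer activations

Layer *l* of an eight-layer hierarchy ("1.0" … "4.1") responds to feature *f*
with gain `exp(−(l−l_f)²/2w²)` (w = 1 layer index), peaking at the planted
layer `l_f`; defaults assign the seven features to layers 1.0, 1.1, 2.1,
3.0, 3.1, 4.0, 4.1 in latency order. Unit activations add unit-variance
noise over 200 units per layer. Any external provider of
stimuli × units matrices per layer can be substituted through the same
container interface — the generator is one provider, a pretrained network
extractor would be another.

## 2. Analysis pipeline

### Annotation preparation

Flattening is row-major with RGB fastest-varying (fixed for
reproducibility). Video annotations are frame-averaged before dimensionality
reduction, and averaging commutes with flattening (property-tested). PCA is
centered, unscaled, fitted on training stimuli only, with 100 components for
the five high-dimensional features; skeleton (28) and action (6) keep native
predictors. Component signs follow a largest-|loading|-positive convention so
stored models are comparable across runs. On desk-scale designs the component
count is additionally capped at `n_train − 1` (the PCA rank bound). No value
normalization is applied to maps before flattening. The Canny edge operator
(Gaussian smoothing σ = 1.0, hysteresis thresholds 0.1/0.3 expressed as
fractions of the maximum smoothed gradient magnitude, making the operating
point intensity-scale invariant) is available for deriving edge maps from
grayscale images.

### Multivariate noise normalization

Noise is defined as the deviation of each repetition from its stimulus's mean
at each timepoint. The channel noise covariance is Ledoit–Wolf-shrunk and the
whitener is the symmetric inverse matrix square root via eigendecomposition
(eigenvalue floor 1e−12 × the largest eigenvalue), estimated on the training
split and applied to all splits. **Where shrinkage enters matters.** Applying
Ledoit–Wolf *within* each (stimulus, timepoint) cell of 5 repetitions × 19
channels yields per-cell shrinkage intensities around 0.8–0.9, and the
average of such estimates collapses toward a scaled identity — whitening
would barely decorrelate anything. The default therefore pools the residuals
of all cells into a single Ledoit–Wolf estimate (algebraically: the average
of per-cell sample covariances, shrunk once at the pooled sample size, where
the intensity is ~1e−4); a `per_cell` mode retains the per-cell variant,
whose off-diagonal *pattern* is shrinkage-invariant and is tested as such.
All epoch timepoints (including pre-stimulus) contribute residuals. The
19-channel posterior subset of a larger montage is a channel-label filter
(`select_channels`), not a hardcoded assumption.

### Decoding

Pseudotrials are means of randomly partitioned bins (30 repetitions → 6
pseudotrials of 5; every repetition used exactly once). Classification is a
linear SVM at fixed C = 1 on the channel pattern of a single timepoint, with
no feature scaling (whitening has already equalized channels). Stratified
sixfold cross-validation holds out one pseudotrial per class per fold. The
full pairwise analysis is repeated 6 times with freshly re-partitioned bins
and averaged; pairs are enumerated in ascending stimulus-id order. Decoding
consumes whitened data by default (a flag selects merely preprocessed data).
Note one sharp edge verified in tests: duplicated class data yields ~0%
cross-validated accuracy, not 50% — each held-out point's twin sits in the
training set with the opposite label (the classic anti-learning artifact) —
so "no information" is asserted as "never systematically above chance".

### Encoding

Ridge is solved in closed form through one SVD of the centered training
predictors, reused across the whole λ grid; with more predictors than samples
this is algebraically the dual (Gram) solution. OLS is the λ → 0 limit
(`include_ols` adds λ = 0, solved by pseudoinverse on the row space). One λ
per feature is selected on the validation split as the argmax of the mean
Pearson correlation over all response cells, ties to the smaller λ; test data
never enter selection (leakage-tested). Training and validation responses are
repetition-averaged per stimulus; test responses are repetition-averaged
before correlating (configurable), which maximizes target SNR and parallels
the noise-ceiling construction. Correlations are computed across test stimuli
within each (channel, timepoint) or (component, layer) cell; constant columns
yield r = 0 with a warning. Layer accuracies weight each component's
correlation by its explained variance, `Σ w_i r_i / Σ w_i`, which reduces to
the plain mean under equal weights (exact).

### Noise ceiling

Per resampling (100 by default): trials of each stimulus are split into two
random halves; stimulus-wise group means are correlated per (channel,
timepoint) half-vs-half (lower bound) and half-vs-all (upper bound). Group
responses are stimulus-wise means — the only construction that yields a
correlation across stimuli. Two derived facts worth knowing: under pure
noise the upper bound converges to √½ ≈ 0.707, not 0, because the half is a
subset of the all-trial group; and the lower bound constrains model accuracy
only where stimulus signal dominates — at low-SNR timepoints a noise-free
model prediction correlates with the 30-repetition mean better than two
15-repetition halves correlate with each other (√(30s) vs 15s as signal
s → 0). Tests compare encoding accuracy to the lower bound at accuracy peaks.

### Inference

Rank p-values are `(1 + #{|null| ≥ |obs|}) / (1 + n_perm)` — the observed
statistic counts into its own null set, so p > 0 always. The sign-permutation
test flips each subject's chance-centered values by ±1; the condition-swap
test reassigns pooled subjects to groups of the original sizes. BH-FDR uses
the step-up adjustment with monotonicity (cross-checked against a literal
brute-force step-up oracle for m ≤ 12). Bootstrap CIs are percentile
intervals over subject resamples; peak CIs resample subjects, recompute the
mean curve, and take its argmax; peak-difference CIs resample the two
conditions independently by default (different subject groups), with a paired
option. Peak ties break to the earliest timepoint / shallowest layer. The
hierarchy test computes Spearman's ρ (average ranks for ties) between the
7-vector of EEG peak latencies and the 7-vector of network peak layers, with
an exact permutation p over all 7! = 5040 orderings of the layer vector;
above 8! orderings a flagged Monte-Carlo fallback is used. The test is
one-sided for positive alignment by default (the scientific question is
whether the hierarchies align), with a two-sided option.

### Orchestration

A master seed fans out through named substreams (one per stage and subject),
so changing, say, the decoding seed never perturbs the simulation. Every
stage records its outputs with content hashes and wall time in
`manifest.json`; re-running resumes after the last intact stage, and two runs
with the same config and seed produce byte-identical result tables. Arrays
live in an HDF5 container (`/design`, `/annotations/<feature>`,
`/eeg/{data,time_ms,trial_table}`, `/activations/<layer>`,
`/design_matrices/...`) with a JSON provenance sidecar; result tables are
plain CSV; configs are YAML.

## 3. Verification problem sizes

The acceptance checks (`tests/test_acceptance.py`, `scripts/acceptance.py`)
run at these sizes, chosen so the whole battery completes in minutes on one
CPU while keeping every statistical bound comfortably powered:

- **Recovery and whitening** — the full default experiment (1440 stimuli,
  5400/5400/900 trials, 19 channels, 70 timepoints); latency recovery over
  10 independent seeds in the test suite, 5 in the acceptance script.
  The whitening check estimates the whitener on the training split and
  measures residual correlation on the held-out test split.
- **Calibration** — 1000 null replicates with 1000 permutation samples each
  (p-value resolution 1/1001, i.e. 2 s.e. ≈ ±0.014 on a 0.05 rate).
- **Null protection** — 20 replicates of a scaled-down group (5 rooms with
  2 held out, 5 subjects, 5/6/5 repetitions, 1000 permutation samples),
  annotation–stimulus assignment shuffled before the encoding analysis.

## 4. What passing tests do and do not show

The generator's noise is Gaussian, spatially exponential, and temporally
white; real recordings have autocorrelated, non-stationary, artifact-laden
noise (an AR(1) temporal option exists in concept but is out of scope, and
no eye-movement or artifact simulation is attempted). The forward model is
exactly linear in the annotations, which is the favorable case for a linear
encoding model; real responses are not. Passing recovery tests therefore
shows the *pipeline* is correct — that whitening, regularization selection,
correlation accounting, and peak inference do what they claim under a known
ground truth — not that real mid-level features behave like the planted
ones. Network activations here are simulated with planted unimodal layer
tuning; plugging in a real pretrained network is an adapter question, not a
pipeline change.

## 5. Known limitations

- Exhaustive hierarchy enumeration caps at 8! orderings; beyond that the
  Monte-Carlo fallback is flagged in the result object.
- The full-design pairwise decoding (16 110 pairs × 70 timepoints × 6 folds
  × 6 repeats) is faithful but expensive by construction; desk-scale configs
  restrict the stimulus count, not the algorithm.
- Per-channel λ, banded ridge, time-generalization, variance partitioning,
  and cluster-based permutation correction are out of scope.
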