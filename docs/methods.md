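# Methods

## The AOI grid

Gaze direction is a pair `(x, y)` with `x ∈ [−1, 1]` (−1 leftward, +1
rightward) and `y ∈ [−1, 1]` (−1 downward, +1 upward), relative to the
phone camera; `(0, 0)` is gaze straight into the lens. The square is cut
into a 4×4 grid of equal cells named row-letter + column-letter, row `A` at
the top (`y` near +1), column `A` at the left; labels are ordered
alphabetically and encoded `AA=0 … DD=15`. The assignment formula is

    col = min(floor((x + 1) / 0.5), 3),   row = min(floor((1 − y) / 0.5), 3).

Cells are therefore half-open (closed at their top/left edge) with the outer
boundary of the square closed, so the map is total on `[−1, 1]²`. The
convention on the measure-zero gridlines is arbitrary; any consistent choice
changes no analysis result on continuous data. Note that the orientation of
the letters (which axis is "row") is likewise a recorded convention: the
four central cells are `BB, BC, CB, CC` under either orientation.

## Frame-quality filtering

A frame is retained iff its detected-face count is 1 or 2 **and** its
gaze-estimation confidence is ≥ 0.75 (the threshold is inclusive: "below
75%" is removed). Frames with two faces are kept because a parent is
usually in view; disambiguating which face is the child's is upstream
tooling's job, not this package's. Removed frames do **not** split a video's
retained sequence — the track is treated as contiguous, since the dwell/
transition structure of interest is much slower than single-frame gaps. An
optional `gap_break` parameter splits tracks at retained-frame-index jumps
larger than a given count, for sensitivity analysis; it is off by default.

## Fixation analysis

A video's fixation profile is the 16-vector of fractions of its retained
frames spent in each AOI (sums to 1). For each AOI, the two cohorts' per-
video fractions are compared with a two-sided permutation test on the
difference of means, Bonferroni-corrected over the 16 AOIs
(0.05/16 = 0.003125, displayed 0.0031). The unit of analysis is the video;
because children contribute several videos the per-video observations are
not independent, which the permutation null ignores — a child-level mode
(`unit="child"`, mean profile per child) is provided for that concern.

## Permutation testing

The statistic is `d = mean(group A) − mean(group B)` and the null
distribution comes from reassigning group labels without replacement.
When the number of distinct splits `C(n_a+n_b, n_a)` is at most the
requested permutation count the test enumerates all of them exactly
(`p = #{|d*| ≥ |d_obs|}/total`, the observed split included); otherwise it
samples `n_perm` random splits and uses the add-one estimator
`p = (1 + #{|d*| ≥ |d_obs|}) / (n_perm + 1)`, which keeps `p ∈ (0, 1]` and
the test valid. Permuted statistics within a relative tolerance of 1e-12 of
`|d_obs|` count as extreme, so exact ties are not lost to float noise. When
many cells are tested on the same units (16 AOIs; up to 120 transition
pairs) one permutation index set is shared across cells — each cell's
marginal p-value is unaffected — and the Monte-Carlo assignment matrices
are built in chunks to bound memory. Reported p-values below the Monte-
Carlo resolution are displayed as bounds ("<.001").

## Scanning analysis

Consecutive retained frames with different AOIs contribute one undirected
transition; dwelling (identical consecutive AOIs) contributes nothing, so
the adjacency matrix has a zero diagonal and occupancy information stays in
the fixation analysis. Each video's matrix is divided by its total
transition count, counting each undirected transition once; consequently the
fractions over unique unordered pairs sum to 1 and a single cell can be read
as "the share of this video's gaze shifts on this edge". Videos with zero
transitions carry no share information and are excluded from cohort means
and tests (with a logged count) rather than imputed. The tested set is the
unique pairs whose pooled (both-cohort) mean fraction is nonzero, fixing a
single Bonferroni divisor; how many pairs are nonzero is data-dependent
(at most 120 for a 16-node graph).

## Sequence classifier

AOI sequences are integer-encoded alphabetically and cut into windows of
`w` frames advanced by `s` (count `floor((n − w)/s) + 1`; a video shorter
than `w` contributes nothing). Each window is one-hot encoded to `w × 16`
and inherits its video's label. The network is a single LSTM layer unrolled
over the `w` frames (input 16, hidden/cell size 64 by default) whose final
hidden state feeds a one-output dense layer and a sigmoid; probability
≥ 0.5 predicts ASD (the boundary value maps to the positive class, a
declared convention). Training: Adam, learning rate 0.001, batch size 5,
class-weighted binary cross-entropy with inverse-class-frequency weights
normalized to mean 1 over the training windows; gradients are clipped to
global norm 5; Glorot-uniform initialization with forget-gate bias +1; at
most 50 epochs with early stopping (patience 5) on validation loss, and the
lowest-validation-loss checkpoint is kept. The LSTM, backpropagation
through time and Adam are implemented in numpy inside the package, which
makes training bit-reproducible from a single seed.

Splits partition **children**, not videos, so window overlap and within-
child correlation cannot leak across sets. The partition is stratified by
diagnosis class so that small cohorts still place both classes in every
split; a split that nevertheless misses a class triggers a warning.
Evaluation is per window by default (every window carries its video's
label); a per-video majority vote (ties → ASD) is available because window
counts per video vary with video length. `grid_search` tabulates validation
macro/weighted precision-recall over a (window, shift) grid and ranks by
validation macro recall.

## Synthetic cohort generator

The generator emulates a study in which each child contributes an
overdispersed number of ~90 s videos (mean 4.7, SD 7.3; 2250 frames at
25 fps) and roughly 43% of raw frames fail quality control. Its parts:

* **Cohort kernels.** Each cohort's AOI sequence is a first-order Markov
  chain with kernel `K = a·I + (1 − a)·1πᵀ` (dwell probability `a = 0.55`),
  whose stationary distribution is exactly `π` and whose undirected edge
  flows are proportional to `π_i π_j`. The NT occupancy puts 0.30 on `BB`,
  0.25 on `BC`, 0.12 on `CB`, 0.10 on `CC` and spreads the rest evenly; at
  `effect_size = 1` the ASD occupancy swaps the `BC`/`CB` masses, and
  intermediate effect sizes interpolate linearly. This plants a fixation
  difference at `BC` (and `CB`) and a transition difference on `BB–BC`
  (and `BB–CB`) while keeping both cohorts centered on the camera region.
* **Child heterogeneity.** Each child perturbs the kernel's row logits with
  Gaussian noise (SD 0.3 by default) and renormalizes — the minimal random
  effect that makes child-grouped splits meaningful.
* **Coordinates.** Uniform over the current AOI's cell by default (the
  simplest null for within-cell position); a truncated-Gaussian mode around
  the cell center (`jitter_sd`) is available. Sampling is arranged so the
  emitted coordinate always maps back to the emitting cell under the
  half-open boundary convention.
* **Dropout.** Each frame independently fails with the configured rate
  (default 0.43); a failing frame keeps plausible coordinates but violates
  exactly one quality criterion, chosen at random: confidence drawn below
  0.75, or a face count of 0 or 3. Both ingest filters are thereby
  exercised, and every dropout frame is actually removed by the filter.

What the generator does **not** emulate: camera motion, per-frame
correlation of confidence with gaze position, annotation errors (wrong but
confident coordinates), within-cell spatial structure, age/sex effects, and
non-Markovian gaze dynamics (saccade sequences, game-phase effects).
Passing tests therefore demonstrate statistical correctness of the
machinery on data with the assumed structure, not performance on real
videos; in particular the classifier's held-out recall on synthetic
contrasts says nothing about the absolute accuracy achievable on real
recordings.

## Problem sizes used by the tests and the acceptance script

The planted-contrast cohort is 15+15 children × 2 videos × 1000 frames
(30+30 videos) with default dropout and child heterogeneity; the null
calibration uses 500 replicate cohorts of 10+10 single-video children with
300 frames and 2,000 permutations; classifier runs use `w=100`, `s=10`,
hidden size 32, at most 12 epochs. These sizes were chosen so the planted
effects are comfortably detectable and the Monte-Carlo intervals are tight
enough to be meaningful. Parameter-recovery checks use single chains of
10⁵–10⁶ frames: with 120 undirected pair categories the expected sampling
total-variation distance is itself ≈ 0.4·√(120/n_moves), so the 0.01
recovery bound needs the longer chain.

## Known limitations

* The permutation tests treat videos as exchangeable units; repeated
  measures per child are only addressed by the optional child-level mode.
* The Bonferroni correction ignores the strong correlation between AOIs
  (a fixation profile sums to 1), making it conservative.
* The numpy LSTM is single-threaded and intended for the data sizes above;
  very large grids of (w, s) configurations will be slow.
* The OpenFace-style importer assumes a linear mapping of gaze angles to
  `[−1, 1]` and is marked experimental (the canonical CSV schema is the
  supported interface).
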