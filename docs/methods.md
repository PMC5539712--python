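# Methods

This note records the models, parameter choices and numerical decisions
behind `emgmodes`, and what the synthetic benchmark does and does not show.

## Signal path

**Filtering.** Every recording is band-pass filtered with a Butterworth
design (`FilterSpec`: order 4, 15–350 Hz) applied forward and reverse
(`scipy.signal.sosfiltfilt`), so the net phase is zero and the effective
attenuation slope doubles. Filtering precedes windowing; edge transients
are not trimmed, because the analysis windows (150 ms, 307 samples at
2048 Hz) are long relative to the filter's impulse response.

**Windowing.** Windows are consecutive and non-overlapping,
N = round(window_ms · fs / 1000) samples; a trailing remainder shorter than
one window is dropped. The default is 150 ms (307 samples at 2048 Hz);
50/100/200 ms are selectable (200 ms ↦ N = 410) to reproduce window-length
comparisons.

**Outlier channels.** Channels with broken contacts are screened once per
recording on the filtered signal: a channel is flagged when its log₁₀ RMS
deviates from the array median by more than `k_mad = 5` median absolute
deviations. The detector is deterministic, permutation-equivariant, and
catches both dead (near-zero) and shorted/amplified channels; an explicit
outlier list in the recording sidecar is honoured in addition. Flagged
pixels are repaired *at the map level*: piecewise-linear interpolation over
a Delaunay triangulation of the good pixel positions, with
nearest-good-pixel fill outside the convex hull. Interpolation never
touches non-flagged pixels.

**Activation maps.** Map pixels are true RMS values (square root of the
mean square). A `ms_scale=True` flag exposes the plain mean square instead;
the two are monotonically related, and consistency between training and
test matters more than the choice. Maps are segmented into per-muscle
sub-maps by configured masks (`ElectrodeArray.muscle_masks`); mask
construction from data is out of scope, and the synthetic generator emits
ground-truth masks.

## The IMS spatial feature

Each array's map becomes a point cloud with one row per electrode and
columns (x = column index, y = row index, v = RMS intensity), standardized
per dimension to zero mean and unit variance so one spherical bandwidth
serves all three axes. A dimension with zero variance (e.g. a constant
map's intensity) is centered but not scaled, avoiding division by zero.

**Bandwidth.** h = factor · mean over points of the distance to the k-th
nearest neighbour, with k = round(0.5 · n) (self excluded, round half-up,
clamped to [1, n−1]) and factor 0.5 by default. Both k-fraction and factor
are `BandwidthSpec` parameters; h scales linearly with the cloud, so the
feature is invariant to uniform map rescaling after standardization.

**Mean shift.** Flat (spherical) kernel: y ← mean of the points within
Euclidean distance h of y. Seeding is deterministic from every data point
(rather than random restarts): identical fixed points, no run-to-run
variance. With a flat kernel the iteration reaches an exact fixed point in
finitely many steps — once the within-h membership set stabilises, the next
step lands on the set mean and stays — so seeds are iterated to
machine-precision convergence (step ≤ 1e−10·h, max 300 iterations), well
inside the advertised fixed-point tolerance of 1e−3·h. Non-converged seeds
are kept but flagged with a warning. Converged centroids within h of each
other merge, keeping the representative whose h-ball contains the most
points; density ties break by seed order (stable sort). This matches the
reference flat-kernel implementation (`sklearn.cluster.MeanShift`) mode
count for mode count at equal bandwidth.

**Mode images.** Modes are inverse-standardized and snapped to the nearest
electrode in the (row, col) plane only (the intensity coordinate is
ignored); coordinates round half-up and clamp to the grid. Two modes
snapping to one electrode leave a single 1 (binary semantics). The three
arrays' binary images, flattened row-major and concatenated in fixed order
(biceps array, triceps array, forearm array), give a vector whose length
equals the total channel count (348 with the default arrays).

A property worth knowing: at bandwidth factor 0.5 the method deliberately
over-segments — the low-intensity background of a map contributes its own
modes besides the activation blobs (mode counts grow rapidly as the factor
shrinks, and collapse to one global mode near factor 1). A planted
activation blob is reliably marked by exactly one mode at its electrode,
but it is not the only mode on the map. The binary image is a spatial
signature, not a blob detector.

**Reduction and composition.** PCA is fit on the concatenated binary
vectors of the *training* split only; the kept dimensionality is the
smallest q whose cumulative explained-variance fraction reaches 0.90. The
reduced spatial vector is concatenated with the five per-muscle intensities
I = log₁₀(mean pixel value of the muscle's segmented map). Intensities
bypass PCA; nothing is rescaled after concatenation (LDA absorbs scale
through its covariance).

## Baseline feature sets

- **ICG** (15-D): the five intensities plus each muscle's center of gravity,
  the intensity-weighted mean (row, col) of its pixels.
- **I** (5-D): intensities alone.
- **TD**: Hudgins statistics per channel — RMS, mean absolute value, zero
  crossings, waveform length, slope-sign changes — concatenated
  channel-major (5 × 348) and PCA-reduced at 90% like the spatial vector.
  ZC/SSC deadzone thresholds default to 0 and are configurable.
- **Diff** (5-D): RMS of one single-differential signal per muscle, from a
  configured pair of adjacent monopolar electrodes.

## Classification and evaluation

LDA uses the pooled within-class covariance with Ledoit–Wolf ("auto")
shrinkage: binary mode columns and their principal components can be rank
deficient on modest training sets, and shrinkage keeps the fit well-posed
without a tuning parameter. Prediction is the arg-max discriminant score;
ties break by class order (classes sorted alphabetically). PCA reducers
and discriminants are always fit on the training rows of each split.

The two-step classifier first identifies the task on the full feature set
with efforts pooled, then identifies the effort with a per-task model
restricted to the muscles involved: biceps + triceps for flexion and
extension; biceps, brachioradialis + anconeus for supination; pronator
teres + anconeus for pronation. Spatial mode columns enter the effort
models by array — biceps/triceps arrays for flexion/extension, and the
*whole* forearm array for supination and pronation (forearm modes are
computed per array, not per muscle); TD columns are filtered to channels
inside the selected muscles' masks. A step-1 error propagates: the effort
is then judged by the wrong task's model, and the joint (task, effort)
label is scored on all 12 classes.

Holdout splits are stratified per class: round-half-up(0.7 · n_class) in
training, then a deterministic adjustment (decrement classes with the
smallest fractional part, later-sorted first on ties) so the global train
count equals round-half-up(0.7 · n_total); 20 repetitions by default. The
long-term protocol trains on the full short-term session and tests on the
first 2 s (13 windows) of each endurance recording — enough delay for
electrode drift, early enough to exclude fatigue. The fatigue protocol
splits each endurance recording into five equal-duration epochs, trains on
the first and tests on all five. A label-permutation control (task labels
shuffled per repetition before training) should sit at chance, 0.25 for
four tasks.

## The synthetic benchmark

The generator emulates the statistical structure the feature pipeline
consumes, not the biophysics. Each channel is band-limited Gaussian noise
(Butterworth-shaped 15–350 Hz spectrum) whose standard deviation follows a
spatial topography: each of the five muscles contributes a 2-D Gaussian RMS
blob on its array (widths ~1.3–2.8 electrode pitches), mixed by per-task
coordination weights and scaled linearly with effort (%MVC / 50). Defaults:

- arrays 8×15, 8×15, 6×18 at 10 mm pitch; fs = 2048 Hz;
- 4 tasks × 3 efforts (10/30/50% MVC) × 10 s short-term trials, plus one
  30 s endurance trial per task at 50% MVC (endurance must span five
  epochs of useful length at 150 ms windows);
- base RMS 100 µV at 50% MVC at the agonist blob peak; additive sensor
  noise at amplitude base/50 (2 µV) — typical surface-EMG noise floors are
  1–2 µV against tens of µV of signal;
- coordination weights with a distinct agonist per task and a
  co-contraction floor of ~0.2 (stabilising antagonist activity keeps even
  "quiet" arrays structured, as in real recordings);
- slow per-channel gain drift (±5%, 0.05 Hz) whose phases are fixed per
  (session, array) — electrode-contact state, shared by a session's trials;
- fatigue in endurance trials only: RMS gain growing by 40% and the upper
  band edge compressing by 35% linearly over the trial, applied in 1 s
  blocks — the two canonical myoelectric fatigue signs.

All randomness derives from a single seed through named `SeedSequence`
streams, so trials are bit-reproducible.

**What passing tests show — and don't.** The generator produces
effort-scaled, task-specific, spatially smooth RMS topographies with
realistic noise, drift and fatigue trends, so end-to-end results
demonstrate that the pipeline recovers spatial structure it is designed
for, that its protocols are wired correctly (train/test hygiene, error
propagation, epoch splitting), and that the feature sets rank sensibly.
They do not demonstrate performance on real HD-EMG: the model has no
motor-unit action potentials, no volume-conductor spatial correlation
between channels (channels are statistically independent given the
topography), no electrode-shift artifacts, and inter-trial variability far
tamer than inter-subject variability. Absolute sensitivities on the
benchmark are therefore optimistic; the directional comparisons are the
meaningful part.

## Numerical details and edge cases

- Degenerate windows (all-zero maps) raise rather than return −∞
  intensities.
- `fit_reducer` on a zero-variance matrix returns an empty reducer with a
  warning; `n_kept` minimality is asserted by tests.
- Confusion-matrix precision is undefined (NaN, excluded from means) for a
  class never predicted.
- Problem sizes in tests: unit tests run on 2 s trials (13
  windows each) for speed; the acceptance layer regenerates the default
  10 s / 30 s benchmark.
- Recording storage is HDF5 (dataset `"emg"`) or delimited text, with all
  metadata in a JSON sidecar; feature tables are CSV with ≥12 significant
  digits.

## Known limitations

- Segmentation masks and differential pairs are configuration, not
  estimated from data.
- No notch filtering or artifact decomposition; the generator produces no
  power-line interference.
- The two-step effort models for supination use the biceps array's modes in
  addition to the whole forearm array; which upper-arm modes feed the
  effort step is a design choice the task description leaves open.
- Mean shift is exact but O(n²) per map; fine for n ≤ a few hundred
  electrodes, not tuned for larger grids.
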