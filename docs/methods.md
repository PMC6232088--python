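# Methods

`mirrormyo` implements a mirror myoelectric interface: a causal pipeline
that maps surface EMG to the positions of a 7-DoF upper-limb exoskeleton,
together with the calibration-transfer schemes used to evaluate how such a
decoder moves between sessions, arms, and tasks, and a synthetic session
simulator that makes every stage verifiable without human recordings.

## The decoding pipeline

**Signals.** Multichannel surface EMG (10 bipolar channels at 2500 Hz, or
1000 Hz in the patient configuration; optionally two 6×4 monopolar
high-density arrays reduced to bipolar derivations) paired with 7-DoF
exoskeleton kinematics at 18 Hz: two forearm translations (mm), forearm
rotation, wrist pronation-supination, and thumb / index /
middle-ring-pinky flexion-extension (degrees). A sample's timestamp marks
the end of its acquisition interval, so the k-th 18 Hz frame sits at
t = (k+1)/18 s and every derived frame is a function of strictly past raw
samples.

**Conditioning.** EMG is band-pass filtered 10–500 Hz (4th-order
Butterworth) and notch filtered at 50 Hz (IIR, Q = 30); kinematics are
low-pass filtered at 1.5 Hz. Filters run forward-backward (zero-phase) by
default because the evaluation replays stored streams; a single-pass causal
variant is available behind `zero_phase=False`. For 1000 Hz recordings the
nominal 500 Hz band edge sits at Nyquist and is clipped to 0.45 × rate
(450 Hz). High-density grids are bipolarized by vertical-adjacent
differences along the fiber direction by default (`scheme="horizontal"`
for the transverse montage).

**Features.** Seven time-domain features per channel on right-aligned
200 ms windows, one output frame per 18 Hz tick (windows overlap by
≈ 144 ms): MAV, unbiased variance, waveform length, RMS, and the
threshold-dependent counters WAMP, ZC, SSC. The counter threshold θ
defaults to 1 % of the window's own RMS — causal and amplitude-relative —
and may be set to any absolute value including 0. The patient variant
replaces the counters with ln(VAR + 1e−12), because counts are not
comparable across arms with different EMG amplitudes. Frames emitted before
one full window of history exist use the growing window and are flagged
warm-up. With 10 channels the seven-feature set yields 70 columns.

**Causal normalization.** Each feature column is z-scored with the mean and
population standard deviation of the trailing 60 s of frames (growing
window before that), emulating the online setting. Three guards make the
online statistic safe: (i) columns whose windowed σ is below 1e−12, or
below 0.1 % of the windowed mean magnitude, emit 0 — a feature that never
varies carries no control information, and its standard score would only
amplify noise (integer count features on quiet channels are the canonical
case: a one-count jump against σ ≈ 0.05 is a 20 σ spike); (ii) normalized
values are clipped to ±10 standard scores, the usual guard against
electrode transients. Scheme runners additionally drop up to one
normalization window (60 s, never more than half the stream) of leading
frames from fitting and evaluation, where the trailing statistics are still
filling up.

**Decoder.** One ridge regression per DoF from the normalized feature
vector to the DoF's position; all feature columns participate in every
DoF's model (no muscle pre-selection — compensatory activations of
unrelated muscles must be visible in the feedback). The fit solves
argmin ‖Xw − y‖² + λ‖w‖² with an unpenalized intercept, via the centering
identity and an SVD of the centered feature block, so heavily collinear
feature sets (MAV/RMS/WL of one channel are near-proportional) remain
numerically stable over the entire λ grid. Ridge's even weight-splitting
across collinear columns is also the mechanism that penalizes
agonist-antagonist co-activation rather than loading one muscle
arbitrarily. Predictions are saturated at the calibration kinematics'
per-DoF range plus a 25 % margin — the exoskeleton cannot execute commands
beyond its travel — and the bounds are serialized with the decoder.

**λ policy.** Within-session decoders select λ per DoF by nested
cross-validation: for each outer training fold, an inner contiguous 5-fold
loop scores each of 15 consecutive powers of ten in [1e−7, 1e7] by mean
inner-validation Pearson correlation, with exact ties broken toward the
larger λ. All transfer schemes use the fixed λ = 1e4.

**Mirroring.** A trajectory transfers between arms by negating the DoFs
whose sign convention reverses under left-right body symmetry — by default
lateral forearm translation, forearm rotation, and wrist
pronation-supination — about a configurable neutral posture (default 0).
The exact flip set and neutral are configuration, not constants: the device
convention is not universal.

**Output smoothing.** Predictions (and, for scoring, the recorded
kinematics) pass a backward weighted moving average: a 550 ms window is
9.9 frames at 18 Hz, rounded to K = 10, with linearly decreasing weights
w_k ∝ (K − k) normalized to sum 1 (10/55 … 1/55); stream-start frames use
the truncated, renormalized weight vector. The smoother is causal.

## Decoding schemes and evaluation

Five schemes cover the transfer structure:

| scheme | calibration | testing |
|---|---|---|
| WS | 4/5 of a session (task-stratified trial blocks) | held-out block, 5-fold CV |
| SS | a previous same-arm session | the new session |
| RSS | previous session + first ~10 min of the new one | remainder of the new session |
| TSAA | one task, other arm, kinematics mirrored | same task, test arm |
| GAA | tasks T1–T4 pooled, other arm, mirrored | any task or free movement |

Evaluation is pseudo-online: stored streams pass through the causal
pipeline exactly as a real-time run would, and smoothed predictions are
compared with smoothed recorded kinematics by Pearson correlation (CC) and
NRMSE per DoF. NRMSE normalizes RMSE by the recorded trajectory's range
over the test stream (σ-normalization is available); a stream whose
recorded range is below 1e−3 device units carries no motion and reports
missing values, which are excluded from aggregates. Metrics are computed
over the concatenated test stream per DoF (a per-trial mode would be
unstable for trials of a few seconds); aggregates are arithmetic means over
DoFs, then tasks/folds/runs.

**Fold construction.** The 5-fold split is stratified by task: each task's
trial sequence is cut into contiguous groups and fold f unions group f
across tasks. A purely sequential split of a task-blocked session would
produce task-pure folds in which some DoFs never move, making CC undefined
and range-normalized error degenerate. Fold boundaries never split a trial;
rest frames stay with the preceding trial. When a task has fewer trials
than folds, its trials are assigned round-robin with a task-dependent
offset so all folds stay populated.

**Stream-matched comparisons.** At desk scale a session lasts minutes, not
the better part of an hour, and the composition of the evaluated stream
dominates scheme differences. Paired contrasts are therefore computed on
identical frames: WS-vs-SS cross-validates the new-day session and
evaluates the previous-day decoder on exactly the same held-out fold
streams (`run_within_vs_session_transfer`); SS-vs-RSS evaluates the plain
transfer decoder on exactly the remainder stream RSS is tested on
(`skip_test_minutes`, snapped to the same trial end). The plain full-stream
runners remain the public scheme definitions. Transfer decoders calibrate
on frames owned by the cued tasks T1–T4; free movement is reserved for
generalization testing.

## The synthetic session simulator

The simulator generates paired EMG + kinematics sessions with the
statistical structure the mirror method assumes.

**Kinematics.** Trials follow the task protocol — minimum-jerk reaches to
four targets on a 70 × 50 cm workspace (T1, 5 s), static distal gestures at
the rest posture (T2, 4 s; pinch, cylindrical, point, supination,
pronation), reach + pointing and reach + grasp compounds (T3/T4, 8 s) —
separated by 2–3 s rests, plus a free-movement mode of minimum-jerk hops
between random workspace waypoints. Reaches adopt a target-dependent
forearm orientation with a per-reach idiosyncratic component so the
orientation DoFs are excited without being collinear with the translations.
In the *active* condition targets, gestures and idiosyncrasies are
randomized per trial; in the *compliant* condition the exoskeleton drives
predefined movements kept constant across the trials of each task, making
the session stream periodic. Task order is blocked (all trials of a task
consecutively, the protocol order) or interleaved.

**EMG.** A nonnegative synergy loading matrix S (channels × 7; the default
10-row matrix mimics the bipolar montage's muscle assignments and has
condition number ≈ 3) maps a per-DoF drive — a tonic postural tone of 0.5
plus the signed normalized excursion from rest (scaled to ±0.5 over the
workspace) plus an optional normalized-speed term (weight 0.2) — to channel
activation envelopes. Each envelope amplitude-modulates a unit-RMS carrier
at the EMG rate, plus white sensor noise at a configurable SNR (default
20 dB). Two carriers exist: band-limited (10–500 Hz) Gaussian noise, the
realistic interference-EMG model whose windowed features carry a few
percent estimation noise; and deterministic per-channel sinusoids at
distinct high in-band frequencies (311 + 13c Hz), which make the features
noise-free functions of the envelopes — the exactly-linear regime used for
parameter-recovery verification. The model is deliberately envelope-scale
only: no motor units, no biomechanics, no EMG-force dynamics — the decoding
pipeline consumes nothing finer.

**Two arms, new days, paresis.** A left-arm session records the mirror
image (sign-convention DoFs flipped) of the intrinsic trajectories while
the EMG derives from the intrinsic drive with the same S — the premise that
healthy inter-limb synergy structure is equal. A new recording day
perturbs the loading matrix: a composition of Givens rotations between
adjacent channel pairs (each shifted electrode senses a mixture of
neighboring sources; negative loadings clipped) plus per-channel log-normal
gain jitter. The study harness uses 25° and σ = 0.1, chosen to produce a
within/across-session performance gap of the magnitude the transfer
literature reports. Post-hoc channel-space perturbation of an existing
session (`perturb_session`) is also provided, but per-channel gain changes
are annulled by the causal z-normalization, so the generation-time loading
perturbation is the one that matters. A "paretic" arm mixes the loading
matrix toward a corruption matrix, (1−γ)S + γC, where C merges adjacent
synergy columns and adds antagonist co-activation, rescaled to the original
column norms — a stand-in for merged post-stroke synergies, not a pathology
model.

**What passing tests do and do not show.** The simulator shares the
method's own assumptions (a fixed linear synergy structure, envelope-scale
coding, exact mirroring). Results on it verify that the pipeline recovers
what the model puts in and that the transfer schemes order as the
assumptions predict; they say nothing about non-stationary muscle activity,
fatigue, crosstalk structure, or any other property of real recordings the
model omits.

## Problem sizes

Desk-scale defaults, chosen so the full verification runs on one CPU in
minutes: scheme experiments use sessions of 4 trials per task plus 40 s of
free movement (≈ 3 min per session; the study's sessions were an order of
magnitude longer), 10 paired seeds per contrast, and an RSS recalibration
window of 2 min (the `minutes` parameter defaults to the protocol's 10);
parameter-recovery runs use 5 trials per task. Mean CC under the realistic
20 dB regime is ≈ 0.76–0.83 for the transfer schemes, comparable in
magnitude to what bipolar-montage continuous decoding studies report.

## Numerical choices

- Ridge: centering + SVD solve; λ = 0 on rank-deficient data is refused.
- λ grid: 15 consecutive powers of ten, 1e−7 … 1e7; inner folds: 5,
  contiguous; tie-break toward larger λ on exact score ties; degenerate
  validation correlations score 0.
- Variance features use the n−1 estimator; logVAR offset ε = 1e−12.
- Normalization: population σ; σ-guards and ±10 clip as above.
- Smoother: K = round(0.550 · 18) = 10; truncated-window renormalization at
  stream start.
- Synchronization matches nearest timestamps within half a frame period;
  session I/O writes shortest round-trip float reprs so read(write(x)) is
  bit-exact.
- Metrics: motion threshold 1e−3 device units; missing values excluded
  from aggregates.

## Known limitations

- The exact overlap convention of the 200 ms windows, the θ threshold, the
  flipped-DoF set, and the NRMSE normalizer are documented choices, not
  reconstructions of the original device software.
- The zero-phase default conditioning is appropriate for stored-stream
  replay; strict real-time deployment would use the causal filter variant
  and incur its phase lag.
- Desk-scale sessions make scheme contrasts sensitive to stream
  composition; the stream-matched runners exist for that reason, and the
  full-stream numbers should not be compared across schemes directly.
- The simulator's paretic mode is a corruption model for testing
  monotonic degradation, not a clinical model of post-stroke synergies.
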