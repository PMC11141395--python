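# Methods

## Signal model

A meal video is reduced to a scalar time series: the mouth ratio
`r_t = ‖p_0 − p_17‖ / ‖p_61 − p_291‖`, the 3D Euclidean distance between
the upper- and lower-lip key points of a 468-point face mesh divided by the
distance between the two mouth corners, evaluated at every frame. Being a
ratio of distances over the same rigid structure it is invariant to where
the face sits in the image, head rotation, and camera distance — the main
nuisance factors of seated-meal recordings. A closed mouth gives a ratio
near 0.1; opening the mouth to receive food drives it towards 1. Frames
where the face detector finds no face are carried as missing values, never
zero-filled (a zero would imitate a closed mouth).

A 2D variant (ignoring the z coordinate) is available via `use_z=False`
for comparison with 68-point 2D-landmark pipelines; the 3D distance is the
default.

## Pipeline and conventions

1. **Outlier removal** (`remove_outliers`): per participant, pooled over
   all of their videos, values with |z| > 3 (population mean/sd, ddof 0)
   become missing. The cutoff 3.0 is the usual convention and is
   configurable; if the pooled sd is 0 nothing is removed (warning).
2. **Smoothing** (`smooth`): trailing (causal) moving average over
   `w = 5` frames; the value at frame t averages the available non-missing
   raw values in `[t − w + 1, t]`, partial windows at the series start
   included. A trailing window was chosen over a centered one so the
   counter can run on a live stream; users comparing against
   centered-window implementations should expect a ~`w/2`-frame onset lag.
   Missing values are excluded from window means, not interpolated; an
   all-missing window stays missing.
3. **Detection** (`ThresholdBiteCounter.detect`): a bite event is a
   maximal run of consecutive frames with smoothed ratio strictly above θ
   (strict `>`, fixed for reproducibility). Runs are debounced by
   construction — consecutive above-threshold frames are one event — and
   each event records onset frame/time, peak ratio and duration. A missing
   frame terminates a run (conservative); `bridge_missing=k` optionally
   carries runs across gaps of ≤ k missing frames, and `min_gap=g` merges
   events separated by ≤ g below-threshold frames. Both default to 0, i.e.
   two above-threshold runs separated by a single below-threshold frame
   are two bites.
4. **Default order**: outlier removal on the raw ratio, then smoothing.
   The pipeline functions compose freely, so the reverse order is a
   one-line change for users who prefer it.

The default pipeline order and the smoothing alignment are genuine design
choices (several orderings are defensible); they are fixed here, and
configurable, so that results are reproducible.

## Threshold search

The counter is exposed as a scikit-learn estimator with a single
hyperparameter θ and no trainable state: `fit` records nothing, `score`
returns `−(1/n)·Σ |predicted_i − annotated_i|` (0 is perfect). Because
nothing is fitted, k-fold cross-validation here measures the *stability*
of a candidate θ across subsets of a participant's meals rather than
generalisation of fitted weights — exactly what one wants when a handful
of meals must pin a single number.

* Folds: `k = min(5, max(2, n_videos))`, shuffled with the configured
  seed; with a single video the search degrades to plain scoring (warning).
* Meal filter: meals with fewer than 10 annotated bites (desserts,
  typically) are dropped from tuning — too few events to inform θ. The
  boundary is inclusive: a 10-bite meal is kept.
* Bounds: θ ∈ [0.05, 1.5] by default. Closed-mouth ratios sit near 0.1
  and bite openings near 1, so the band safely brackets any plausible
  threshold; grid step 0.01, 60 random-search draws, 30 Bayesian
  iterations, all configurable.
* Grid and random search run through scikit-learn's `GridSearchCV` /
  `RandomizedSearchCV`; a post-pass breaks exact score ties toward the
  smallest θ (deterministic and documented). The Bayesian option is an
  in-package 1-D sequential model-based optimiser: a Gaussian-process
  surrogate (Matern 5/2 + white noise, scikit-learn) over evaluated
  (θ, score) pairs, expected-improvement acquisition over a dense random
  candidate pool, with the first third of the budget (≥ 5 points) spent on
  uniform exploration. All three methods are seeded and reproducible.
* The objective is piecewise constant in θ (counts are integers), so
  optima are flat bands; any point of the best band is equally valid and
  the tie-break makes the choice deterministic.

**Leave-one-out transfer**: a participant with no annotation receives the
unweighted mean of all other participants' tuned thresholds (by
convention, from random search — the configuration is free to use
another method). With n tuned participants this yields n transferred
thresholds, each independent of its target's own data.

## Accuracy arithmetic

Accuracy compares *pooled* counts, never per-event matches:
`A = |100 − 100·|P − T|/T|` for annotated total T > 0 and predicted total
P. The inner term is 100·(1 − relative absolute error); the outer absolute
value folds the result back to positive when P > 2T. Fold-back figures
flatter gross over-counts (a 2.7× over-prediction reports 65.7%), so the
report emits a warning for every such row and `clamp_at_zero=True`
substitutes max(0, ·). Report tables round to one decimal, half-up.
Group reports pool counts *before* applying the formula (a mean of
per-video accuracies is a different statistic, available behind
`per_video=True`). Summary rows give the unweighted mean and sample
(ddof 1) standard deviation of the group accuracies; the sd convention in
the source tables this package reproduces could not be pinned down exactly
under either ddof, so sds are reported but not used as reference values.
Descriptive statistics (`summary_stats`) use the smallest most-frequent
value as the mode and linear interpolation between closest ranks for
quartiles; rank correlation is Spearman's ρ with average ranks on ties
(undefined, and an error, for constant input).

## Synthetic data

The generator exists so that every stage is testable against exact ground
truth without any video. A trace is

```
r_t = baseline + chew_t + bites_t + noise_t
```

with baseline 0.12 (closed mouth), a chewing sinusoid of amplitude 0.06 at
1.5 Hz, raised-cosine bite bumps of amplitude 0.55 and width 0.6 s at
onsets ≥ 2 s apart (jittered), and Gaussian noise of sd 0.01, at 30
frames/s — magnitudes chosen to match what the mouth ratio of a seated
eater actually does. Chewing is gated off inside each bump (one does not
chew mid-bite), which also keeps every bump a single threshold crossing.
The configuration invariant `3·noise_sd + chew_amplitude < bite_amplitude`
guarantees bumps clear the noise floor.

Each trace carries its ground truth: planted onsets and the **separating
band** — the open interval of thresholds that, in the noise-free limit and
after the 5-frame smoothing, recovers exactly the planted count. The band
is computed from the noise-free rendering itself (maximum of the smoothed
signal outside bump supports; minimum over bumps of the smoothed peak),
shrunk only by a float-safety sliver, so detector-closure properties hold
by construction rather than by tolerance.

Cohorts default to the validation study's shape — 15 participants with
(10, 14, 14, 13, 11, 6, 14, 14, 13, 13, 7, 12, 8, 9, 6) videos, 164 in
total — with per-participant jitter of baseline/amplitudes (distinct true
bands), per-video counts ≈ 41 ± 15 clipped to [5, 90] (so sub-10-bite
meals exercise the tuning filter), and texture labels that modulate bump
width and spacing (soft: larger, sparser bites; hard: smaller, denser).
`jitter=False` produces a homogeneous cohort where one threshold is
perfect for everyone — the regime where leave-one-out transfer must be
exact. The landmark-level generator embeds any trace into a full 468-point
stream (corners fixed 0.2 apart, lip separation = 0.2·r_t) so the I/O and
ratio stages can be tested end to end.

What the generator deliberately does **not** emulate: head pose changes,
occlusion (hands, cutlery), lighting, face-detector dropouts correlated
with movement, and drift in landmark calibration. Passing synthetic tests
therefore demonstrates the correctness of the signal processing, search
and evaluation machinery — not robustness of the landmark stage on real
video, which is bounded by the face-mesh backend.

## Sizes and determinism

Test and acceptance runs use scaled-down cohorts (3–4 participants, 3–5
meals each, ≈ 14 bites per meal) — the arithmetic being verified is
size-independent, and the published-table reproductions are exact desk
calculations on the bundled totals. All randomness (trace noise, onset
jitter, fold shuffling, random/Bayesian search) flows from explicit seeds;
repeated runs are bit-identical.

## Known limitations

* Chew counting is out of scope: chewing barely moves the mouth ratio,
  which is precisely why it is modelled as sub-threshold oscillation.
* Per-event matching against annotation timestamps is not implemented;
  accuracy is defined on per-meal totals only.
* The fold-back accuracy convention can mask gross over-prediction — the
  warnings and `clamp_at_zero` exist for this reason.
* A single threshold per participant assumes mouth-opening amplitude is a
  stable personal trait across meals; participants with erratic eating
  styles will tune poorly, and the transferred (leave-one-out) threshold
  is only as good as the cohort's homogeneity.
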