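# Methods

## Model and assumptions

`pupilkit` treats pupil size change as the output of linear time-invariant
(LTI) systems driven by visual events. Two event streams are extracted per
visual-field region from the stimulus video: the signed luminance change
(cd/m² per step) and the contrast change (its absolute value). The sustained
component is the time-cumulated convolution of the luminance trace with a
gamma-shaped response function (RF): a step to brighter settles the pupil at
a smaller size. The transient component is the (non-cumulated) convolution of
the contrast trace with a second RF, modeling the short-lived orienting
constriction elicited by any salient change regardless of direction. Both
components therefore share one sign convention — constriction is negative —
and combine linearly as `luminance + w_contrast · contrast`.

Assumptions inherited from the LTI framing: responses to successive events
superpose additively, the RF does not change over a recording, and response
amplitude is linear in event magnitude (approximately true for the moderate
luminance ranges of typical video; strong flooring/ceiling at extreme
luminance is not modeled).

## Event extraction

* RGB → CIELAB L\* under sRGB/D65 (scikit-image), rescaled to 0–255. The
  display's native primaries are not characterized.
* Display gamma curve `Lum = Lum_max · (L*/255)^γ`; defaults γ = 2.2 and
  Lum_max = 212 cd/m² describe a consumer OLED panel and should be set to
  the measured values of the experiment display.
* Luminance change at frame *t* is `mean(t) − mean(t−2)`: a lag-2 sliding
  difference at the native frame rate, i.e. an 80-ms comparison window at
  25 Hz, emitted densely (one value per frame). The first two frames are
  referenced to a black frame, so a movie's onset itself is an event. The
  lag is configurable.
* Gaze contingency: each luminance frame is placed on a zero-luminance
  canvas 1.5× the screen (same aspect ratio) with the gaze pixel at the
  canvas center. Black surround matches a dark testing room. Gaze is
  downsampled to one sample per frame by averaging valid samples within each
  frame interval; frames without valid samples carry the last valid position
  forward (screen center before the first valid sample). Off-screen gaze is
  clamped to the screen bounds so the canvas never goes empty.
* Region grid: 6 rows × 8 columns tiling the canvas; with non-divisible
  resolutions the right/bottom regions absorb the remainder pixels. The six
  weight groups split rows into top/bottom halves and columns into
  eccentricity bands symmetric about the vertical midline: central = the two
  innermost columns, middle = the next two per side, peripheral = the
  outermost column per side. The exact banding of eight columns into three
  eccentricities is a package choice; any symmetric banding is expressible
  by subclassing `RegionGrid`.

## Response functions

Both families start after a fixed 200-ms onset delay (the pupil's response
latency) and default to a 4-s kernel support, which covers the slowest
defaults with room to spare.

* Erlang gamma `h(t) = t^n e^{−nt/t_max}`: peak at `t_max` regardless of
  `n`; `n` sets width. Kernels are peak-normalized (computed in log space —
  the raw peak `t_max^n e^{−n}` underflows for realistic `n`), so the
  amplitude parameter reads directly as peak response. This is the default
  family because its parameters are separable and interpretable.
* Gamma probability density `d(t) = c/(θ^k Γ(k)) t^{k−1} e^{−t/θ}`: area
  `c`, peak at `(k−1)θ`; timing and shape interact. Provided for
  compatibility with the two-LTI event-related tradition.

Because predictions and observations are z-scored, the absolute RF amplitude
is not identifiable in the continuous model and is fixed at 1; only the
*relative* contrast weight is fitted.

## Fitting and evaluation

Free parameters (full-field model, Erlang family): luminance `n`, `t_max`;
contrast `n`, `t_max`; contrast weight — five parameters, matching the
degree of the polynomial control model. The regional variant adds five
weights W2–W6 (W1 ≡ 1 as the reference; a global weight scale is absorbed by
z-scoring, which is why one weight must be pinned).

* Loss: RMSE between per-trial z-scored observed and predicted traces,
  pooled over trials. Observations are linearly interpolated onto the event
  timestamps; blink gaps ≤ 500 ms are linearly interpolated, longer gaps
  stay masked and excluded — standard pupillometry practice.
* Optimizer: Nelder–Mead with box bounds, `xatol 1e-4`, `fatol 1e-8`,
  adaptive simplex for > 5 free parameters. Starting values `n = 10`,
  `t_max = 0.3 s` (luminance), `n = 3`, `t_max = 0.5 s` (contrast), contrast
  weight 0.5, weights 1; bounds `n ∈ [0.5, 40]`, `t_max ∈ [0.05, 2] s`,
  weights ∈ [0, 10]. These keep kernels well-formed across the plausible
  physiological range. Restarts (jittered starts) are available via
  `FitConfig.n_restarts` for harder landscapes; the default is a single
  start, which suffices on the synthetic test surfaces.
* Cross-validation: trials are split at random into 70% training / 30%
  testing, independently re-drawn for each of five folds (repeated random
  splits, not a partition — a trial may never appear in a test set).
  Reported metrics are test-set means across folds. `FitResult.params`
  carries the fold with the lowest training RMSE.
* Metrics: `R² = 1 − SS_res/SS_tot` on z-scored series, Pearson r, RMSE, and
  `BIC = n·ln(RSS/n) + k·ln(n)` computed on the pooled held-out residuals of
  all folds with k = number of free parameters. BIC inputs are a declared
  package convention.

## Event-related benchmarks

* Event detection: keep samples with |change| ≥ 3 cd/m², then greedily scan
  in time order and drop events within 1 s of the previously kept one
  (earliest-first pruning is a declared tie-break; alternatives change event
  counts).
* Epochs: 3-s segments at the pupil sampling rate from each event onset,
  baseline-corrected by the mean of the first 250 ms (the pre-response
  window), then jointly scaled by one pooled SD. Epochs overrunning the
  recording are skipped. Full-length epochs are kept even if a later event
  falls inside them; the separation rule limits crosstalk.
* Two-LTI fit: RF1 (gamma density) fitted through its cumulative to the
  dilation grand mean; RF2 fitted to the constriction-minus-inverted-dilation
  difference; the LTI2 weight enters linearly and is solved by ordinary
  least squares, with weight 0 when the overshoot is numerically negligible
  relative to the dilation.
* Discrete contrast-response model: event magnitudes binned at the
  20/40/60/80th percentiles (ties to the lower bin); sustained + transient
  Erlang RFs, a contrast weight, and a global gain (mapping cd/m² to z
  units) fitted to the five bin-mean epochs with the same baseline
  correction applied to predictions.
* Polynomial control: one degree-5 polynomial of within-trial time (scaled
  to [0, 1] for conditioning), least-squares fitted jointly across trials.

## Synthetic data

The generator emulates the statistical structure the model assumes: videos
with piecewise-constant (optionally per-region) gray levels — by default
64×48 px, 25 Hz, 60 s, 10 steps spaced ≥ 2 s (a dense preset with 0.2–0.8 s
spacing stresses superposition) — gaze traces at 500 Hz, and pupil traces
generated by the forward model plus i.i.d. Gaussian noise in z-units at
500 Hz. Default truth parameters (luminance RF n = 13.7, t_max = 0.28 s;
contrast RF n = 3.0, t_max = 0.53 s; contrast weight 0.42; regional weights
(1, 0.8, 0.5, 0.9, 0.7, 0.4); noise SD 0.5) describe a realistic observer
with the expected central > middle > peripheral and top > bottom visual-field
anisotropy.

What the generator does **not** emulate: naturalistic movie statistics
(continuous, spatially structured luminance flux), autocorrelated
physiological noise, blinks/saccade kinematics, foreshortening error, or any
cognitively driven pupil dynamics. Passing recovery tests on this data shows
the estimation machinery is correct and well-conditioned — not that the model
captures all variance of real recordings, where explained variance is far
lower.

## Numerical choices and limitations

* Convolutions use FFT-based routines; agreement with direct summation is
  verified to 1e-10 in tests.
* Zero-variance traces z-score to all-zeros with a degeneracy flag rather
  than raising inside hot loops; degenerate fit inputs raise typed errors.
* Problem sizes in the test suite and the reproduction script (10 trials of
  60 s for recovery, 6 per-region trials for weight recovery, 4 trials for
  pipeline concordance) were chosen as the smallest sizes at which all
  parameters are well-identified.
* Video container decoding depends on the imageio plugins present at run
  time; the library API operates on frame arrays and `.npy` stacks directly,
  so all analyses are reproducible without any codec.
* Known limitations: rectangular (not elliptical/cortically magnified)
  visual-field grid; one shared weight set for both components; no color,
  spatial-frequency, or cognitive event streams; simplex optimization is
  local (use restarts for high-dimensional variants).
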