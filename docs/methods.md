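# Methods

This note documents the modeling choices behind `eegage`: what is computed,
which parameters matter, what the synthetic cohorts do and do not emulate,
and where the design was genuinely open.

## Preprocessing

The chain is fixed in order: canonicalize channels → resample → common
average reference → band-pass → artifact mask → segmentation → retention →
STFT.

* **Channel canon.** Recordings are reordered to a fixed 19-name 10-20 list
  (Fp1 … Pz); vendor spellings (`EEG Fp1-Ref`, `T7/T8/P7/P8`) are normalized
  and non-scalp channels (auricular references, ECG …) dropped before
  re-referencing, so the average reference is computed over scalp channels
  only.
* **Resampling** is polyphase FIR (anti-aliased); only downsampling is
  allowed since the working rate (200 Hz) is below clinical acquisition
  rates. **Band-pass** is a zero-phase linear-phase FIR (401 taps by
  default, applied forward-backward), passband 1–70 Hz; at 200 Hz this gives
  ≥ 20 dB attenuation at 0.1 Hz and 90 Hz while passing 10 Hz within 5%.
* **Artifact definition.** A time sample is artifactual when |amplitude| >
  200 µV on *any* channel. The alternative (per-channel masks) would make the
  artifact proportion channel-dependent; the any-channel reading yields the
  single per-segment scalar the retention rule needs. The artifact
  proportion of a segment is its fraction of masked *samples* (not windows
  or channels). Masking happens after filtering, i.e. on the signal the
  model would otherwise see.
* **Segmentation** uses a 300-s window stepped by 30 s (both configurable);
  a recording shorter than one window yields zero segments, which is logged,
  not an error. Retention keeps artifact fractions strictly below 0.30.
* **STFT.** 4-s Hanning (periodic) windows, 50% overlap, frames anchored at
  sample 0, so a 300-s segment at 200 Hz gives T = (60000−800)/400+1 = 149
  frames; the 0.25 Hz grid truncated to [1, 40] Hz *inclusive* gives F = 157
  bins. The spectrogram scale is log-power, `log(|X|² + ε)` with ε = 1e−10;
  magnitude and plain power are available (`spec_scale`). Log compression
  keeps the dynamic range of the features small, which matters for the
  recurrent layers downstream.

## Filter layer

Corner frequencies of the M triangular bands are M+2 points uniform on
`v = 26·log10(1 + f/7)` between 1 and 40 Hz, mapped back to Hz and snapped
to the nearest 0.25 Hz bin; strict increase is enforced after rounding, and
the outer corners are pinned to the band edges. Each mask column rises
linearly to exactly 1 at its center bin and falls linearly to 0 — unimodal
by construction, with support width non-decreasing in frequency (the
monotonicity is exact for M ≤ 32 at F = 157; beyond that, bin rounding can
introduce ±1-bin jitter between neighboring widths). The effective filters
are `σ(W) ⊙ W_L`, so the trainable part can only attenuate within the
triangular envelope, never move or widen a band. `W` is shared across
channels and initialized N(0, 1), putting the initial gates near 0.5.
M is a required choice with default 32 (16 in the reduced desk-scale
configuration); it is a capacity/resolution trade-off, not a tuned constant.

## Network and optimization

Per frame, the C×M filter outputs are flattened to one feature vector
(channels vary slowest); two unidirectional GRU layers (hidden 64) process
the T-frame sequence; attention pooling scores each frame by
`tanh(a_j · w_att)` (w_att is a vector, i.e. an H→1 score map) and
softmax-normalizes over frames; a trainable affine map H→1 plus softplus
produces the age. The affine head is the minimal bridge between the
H-dimensional pooled vector and the scalar softplus input. Inputs to the
filter layer are z-scored per (channel, frequency-bin) using training-set
statistics (`standardize=True`); this is an optimization aid and the
statistics are part of the checkpoint.

Everything is float64 numpy. Backpropagation through the whole stack is
hand-derived and checked against central finite differences (relative error
< 1e−5 in the test suite). The loss is MAE on predicted vs chronological
age per segment (MSE available); the optimizer is Adam (lr 1e−3, β =
0.9/0.999). No dropout or normalization layers are used. Determinism: all
randomness flows through `numpy.random.default_rng(seed)`; on a fixed
machine and BLAS, training and inference are bit-reproducible.

Epoch selection: among epochs with `deltaMAE ≤ 0.5` years, take the lowest
`meanMAE`; ties resolve to the earliest epoch; if no epoch qualifies the
global `meanMAE` minimum is returned with a warning. The 0.5-year tolerance
quantifies "train and validation stay consistent" and is configurable.

## Splits, inference, statistics

Splits are 8:1:1 by recording (floor for validation/test, remainder to
train — 772 recordings give 618/77/77; small cohorts always get at least
one recording per subset), seeded, optionally stratified over age deciles
by largest-remainder allocation. A subject-level split mode keeps repeat
recordings of one child together and is recommended when subjects repeat;
recording-level remains the default.

A recording's BA is the median of its segment predictions (even counts:
midpoint of the central pair). Zero retained segments is an error naming
the recording.

Statistics follow standard definitions: two-sided p throughout; paired test
of gaps = one-sample t vs 0 with Cohen's d = mean/sd of the gaps; R² is the
squared Pearson correlation of BA vs CA (a 1−SSE/SST variant is available —
the two differ when predictions are biased); the independent-samples test
defaults to Welch; the RM-ANOVA is one-way within-subject with df (k−1,
(k−1)(n−1)), no sphericity correction, partial η² = SS_effect/(SS_effect +
SS_error), and post-hocs are all pairwise paired t-tests with p multiplied
by the number of comparisons (capped at 1). The ANOVA is computed via
pingouin and cross-checked in the tests against a direct sums-of-squares
computation. `paired_gap_test_from_summary` recomputes t = mean/(sd/√n)
from printed group summaries, which is how published group tables can be
verified without subject-level data.

Matched-control sampling visits cases in seeded random order and greedily
takes the nearest-age unused control within the case's sex stratum (pooled
when no sex column exists); it errors when a stratum runs dry rather than
matching across sexes.

## Synthetic cohorts

Each simulated recording is: a per-channel 1/f^β background (β = 1,
15 µV SD), white sensor noise (5 µV), a posterior dominant rhythm, and
artifact bursts. The rhythm is a sinusoid at
`f_pdr(age) = 10 − (10−6)·exp(−age/4)` Hz — ~8.1 Hz at age 3, ~9.9 Hz at
age 14, the textbook maturation of the occipital resting rhythm — with a
slow (~0.1 Hz) waxing-waning envelope, amplitude 30 µV on O1/O2 fading
anteriorly (occipital 1.0 → frontopolar 0.08). Artifacts are Poisson-placed
(1/min default) 0.5-s bursts of an 8 Hz oscillation under a Hann envelope at
1.5×300 µV; the in-band carrier makes them survive the 1–70 Hz filter that
precedes masking, as broadband movement/EMG artifacts do. Ages are uniform
over 3–14 years. All values are configurable; the defaults were chosen once
on qualitative developmental-EEG grounds.

What the simulator does **not** emulate: inter-subject variability of the
maturation curve (f_pdr is a deterministic function of age, so the age
signal is cleaner than in real cohorts), spatial correlation structure
beyond the PDR topography, eye-blink/ECG artifact morphology, drowsiness
and sleep, and any diagnosis-specific EEG signature (a uniform gap offset
can be added to a simulated case group for exercising the statistics).
Passing the recovery test therefore shows the pipeline and model can
extract a physiologically shaped spectral age signal end to end — it does
not certify real-data accuracy.

## Desk-scale experiment sizes

The standing recovery experiment uses 120 subjects (ages 3–14), 6-min
recordings, 60-s windows with 30-s step (11 segments each), a 16-band
filterbank, hidden size 64, 30 epochs, batch 64 — about 4 minutes on one
CPU, reaching held-out r ≈ 0.98 and MAE ≈ 0.5 years. The determinism check
uses a 10-subject cohort with 3 epochs. These sizes are the package's
reference configuration for reproducible CPU-only experiments; the
architecture is unchanged at full scale (M = 32, 5-min windows, hundreds of
epochs), only slower.

## Numerical details and edge cases

* softplus is computed as `logaddexp(0, x)`; attention softmax subtracts the
  per-sample max; sigmoid is `scipy.special.expit`.
* Zero-variance inputs to correlation/t-tests raise instead of returning
  NaN; an all-equal gap matrix reports F = 0, p = 1 (the 0/0 case is
  resolved by the zero-effect convention, with a relative tolerance for
  float dust).
* Filter-bank construction fails loudly when M is too large for distinct
  rounded corners at the given resolution.
* `deltaMAE ≥ 0` and `meanMAE ≥ deltaMAE/2` hold by construction; histories
  must be appended with consecutive epoch numbers.
* Checkpoints are single `.npz` archives (schema-versioned JSON header,
  filterbank mask/corners, all weights, standardization statistics, full
  history); loading restores a predict-ready estimator.

## Known limitations

* No ICA/regression artifact removal, electrode interpolation, or sleep
  staging — the caller asserts wakefulness.
* The whole-brain/regional models share no weights; training all six
  regions multiplies cost by six.
* MAE-based selection on segments treats segments of one recording as
  independent samples; recording-level leakage between train and validation
  is prevented by splitting at the recording (or subject) level before
  segment expansion.
* Printed group tables can be internally inconsistent; the summary-based
  t recomputation makes such checks explicit instead of hiding them.
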