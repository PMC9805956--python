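# Methods

`pupcall` implements an analysis chain for mouse-pup isolation
ultrasonic vocalizations (USVs): syllable detection from ultrasonic
audio, per-syllable acoustic featurization, alignment of syllables with
a scored behavior ethogram, cross-covariance between non-vocal movement
intensity and USV rate, and kernel two-sample (MMD) comparison of
syllable repertoires. A synthetic-trial generator with fully known
ground truth drives development and validation.

## Syllable detection

Audio (250 kHz sampling) is transformed to a one-sided power
spectrogram (Hann window, `nperseg = 1024`, `noverlap = 512`: a
4.096-ms analysis window with a 2.048-ms hop and 244-Hz bins — enough
temporal resolution to resolve 5-ms syllables). Within the 25–110 kHz
band, each frame yields:

- **mean frequency** — power-weighted mean of the band bins;
- **spectral purity** — power of the strongest bin divided by total
  band power;
- **dominant frequency** — frequency of the strongest bin, refined to
  sub-bin accuracy by parabolic interpolation of log power at the peak
  and its two neighbors;
- **spectral discontinuity** — absolute change of dominant frequency
  from the previous frame, in kHz (0 for the first frame). The quantity
  is not given a closed-form definition in the literature that motivated
  this threshold cascade; the inter-frame dominant-frequency jump is our
  interpretation, and both the definition's band and the threshold are
  configurable.

A frame passes iff mean frequency > 45 kHz AND purity > 0.3 AND
discontinuity < 1.00 kHz. Runs of passing frames become candidate
syllables; candidates separated by less than the 30-ms minimum
inter-syllable interval are merged **first**, and merged candidates
shorter than the 5-ms minimum duration are discarded **second**. The
order matters for borderline cases (two nearby sub-threshold fragments
can jointly form a valid syllable — e.g. a call whose midpoint pitch
jump fails the discontinuity criterion for one frame) and is tested.
Segment times are half-open `[onset, offset)` seconds from file start,
with `onset = first passing frame center − hop/2`. Silence on either
side of a tone tapers detection by at most one–two frames, so onsets
land within two hops of ground truth.

With the band spanning ~350 bins, white noise has expected purity
≈ (ln 350 + γ)/350 ≈ 0.02, far below the 0.3 criterion, so background
frames essentially never pass; the purity criterion is what gives the
cascade its specificity, while the mean-frequency criterion rejects
low-frequency broadband sounds.

## Acoustic features

Eight features per syllable: duration (ms); inter-syllable interval
(onset-to-onset, null above 400 ms — longer gaps are bout boundaries,
not rhythm); mean pitch (kHz); pitch slope (kHz/ms); band-limited mean
frequency and its standard deviation across frames; spectral purity;
and the frequency-modulation (FM) index, the sample standard deviation
of `log(f(τ)/mean pitch)` over duration-normalized time τ ∈ [0, 1].
Natural log is used (the base only rescales the index by a constant);
all standard deviations are sample (n−1) statistics.

Pitch features come from the dominant-frequency trace. Frames whose
analysis window straddles a syllable edge mix call and background
energy and bias the endpoint dominant frequencies by up to
`slope · window/2`; we therefore use only frames whose window lies
fully inside the syllable, and linearly extrapolate the trace to the
exact onset and offset. Mean pitch is the time-weighted (trapezoid)
average of that boundary-extended trace over the full syllable, and
slope is the extrapolated end-to-start difference divided by duration.
For a linear chirp this recovers the programmed slope and mean pitch
essentially exactly (≲ 0.05 bin), independent of how the frame grid
falls relative to the syllable; syllables too short for two interior
frames fall back to all spanned frames, and single-frame segments are
flagged with slope and spread set to 0. Mean frequency and purity are
frame values averaged across the syllable (the aggregation is a
package choice; the features are defined per frame).

Per-mouse aggregation applies strict-inequality inclusion thresholds
(a mouse with exactly 50 syllables fails a "> 50" rule), reports
excluded mice explicitly, and bins duration/pitch distributions at
2 ms / 2 kHz by default.

## Behavior alignment

An ethogram is an ordered set of half-open intervals over
{locomotion, wriggling, lying_still, grooming} that must tile the
session exactly; gaps or overlaps raise a validation error listing the
offending intervals. Each syllable is coded by the behavior at its
**onset** (a syllable spanning a transition belongs to the behavior in
which it started); a boundary onset belongs to the interval beginning
there. USVs-per-second-of-behavior is count/time per behavior (null
when the behavior never occurred), which conserves the total count:
Σ_b rate_b · time_b = N. Rate shares renormalize the per-behavior
rates to sum to 1, removing the influence of behavior prevalence.

## Movement–USV-rate cross-covariance

The movement trace (one scalar per video frame; 30 fps default,
frame i stamped at (i+0.5)/fps) is smoothed with a 90-frame centered
moving average (3 s at 30 fps; shrinking windows at the edges) and
linearly interpolated at the centers of the USV-rate bins (syllable
counts in 3-s bins). The coefficient-scaled cross-covariance

    c(ℓ) = Σ_t (a_t − ā)(b_{t+ℓ} − b̄) / sqrt(c_aa(0) · c_bb(0))

normalizes each vector so its lag-0 auto-covariance is 1, bounding the
curve in [−1, 1] and making trials poolable. Positive lag means the
second series (USV rate) follows the first (movement). The FFT-based
implementation is tested to 1e-10 against the O(n²) definition.

Each trial's two 5-min sessions give a **matched** curve (mean of the
two same-session pairings) and a **shuffled** curve (mean of the two
crossed-session pairings) — an empirical null with identical marginal
statistics. Sessions with zero USVs have zero rate variance, so the
normalization is undefined; such trials are excluded and logged. The
group-level covariance coefficient (CC) is the maximum of the mean
pooled matched curve within |lag| ≤ 5 s (with 3-s bins the reachable
lags are −3, 0, +3 s; ties resolve to the lag nearest 0), and each
trial's matched and shuffled CCs are read off its own curves at that
pooled lag — so the matched−shuffled difference is unbiased even
though the pooled CC itself is a maximum.

## Repertoire comparison (MMD)

Squared maximum mean discrepancy with an RBF kernel, unbiased
U-statistic by default (the biased V-statistic, which is nonnegative
and exactly zero for identical multisets, is selectable; note the
unbiased estimator is slightly negatively biased when the two samples
share duplicated points). Bandwidth defaults to the median pairwise
distance of the pooled sample. The default embedding is the
standardized (pooled z-score) eight-feature vector; externally
computed latent embeddings can be substituted, making the protocol
embedding-agnostic. Null inter-syllable intervals are imputed at the
400-ms cap before embedding (an excluded interval carries no finer
information than "long").

Raw MMD values have no absolute scale, so each between-group contrast
is read against a within-group baseline: the distribution of MMDs
between random halves of one group's **pups** (splits at the pup
level, never the syllable level, so pup identity cannot leak across
the split). A permutation-test utility is provided but optional: the
protocol reports values against baselines rather than p-values.

## Synthetic trials

The generator produces, per 5-min session (deterministically from a
seed):

- **Ethogram** — behavior bouts with Gamma(3, 5 s) durations clipped to
  [2, 60] s, behavior drawn i.i.d. from the configured mix (long-run
  time proportions match the mix in expectation; the tiling is exact).
- **Movement** — per-behavior mean levels (locomotion 1.0, wriggling
  0.8, grooming 0.6, lying still 0.05, arbitrary units), plus Gaussian
  noise, rectified at zero and smoothed with a 0.5-s moving average.
  This is the simplest nonnegative process with behavior-dependent
  levels and realistic autocorrelation; it is *not* a biomechanical
  model.
- **USV onsets** — inhomogeneous Poisson process with rate
  `baseline + gain · movement(t − lag)`, realized exactly by thinning a
  homogeneous stream at the rate's upper bound. Defaults
  (baseline 0.1 s⁻¹, gain 0.8 per movement unit) give session totals of
  order 10², in the range observed for vocal pups. A fixed-count mode
  (uniform onsets with a minimum 150-ms gap) supports controlled
  detector benchmarks.
- **Syllables** — linear chirps with an optional midpoint pitch jump,
  1-ms raised-cosine edge tapers, summed over white noise. Age profiles
  program the developmental trends reported for pup isolation calls:
  P5/P10-like profiles have ~21–22 ms durations and bimodal pitch
  (modes near 55/85 and 60/88 kHz); the P15-like profile has ~11 ms
  durations and unimodal pitch (75 ± 6 kHz). Slopes are uniform within
  ±0.35 kHz/ms and 30% (P5/P10) or 5% (P15) of syllables carry an
  8–15 kHz jump. Amplitude and noise floor (default 1.0 over 0.05,
  ≈ 23 dB broadband SNR) are package choices — syllable amplitude/SNR
  statistics are not something we calibrate to published values.

What the generator does **not** emulate: harmonics and nonlinear
phenomena, reverberation and microphone directionality, multi-animal
audio, amplitude modulation within syllables, and behavior-dependent
syllable acoustics (syllable parameters are independent of the
ethogram). Passing tests therefore demonstrate correctness of the
*analysis* under the generator's assumptions, not detector performance
on degraded real recordings.

## Numerical choices and problem sizes

Spectrograms are computed in single precision (ample for the frame
metrics, including sub-bin peak refinement, and ~4× faster on long
ultrasonic recordings); a double-precision path remains available. All
randomness flows from explicit seeds through `numpy.random.Generator`;
fixed seed implies bit-identical outputs, which the tests assert.

Validation problem sizes: detector fidelity uses 20 trials of 60 s with
50 syllables each; coupling recovery uses 20 replicates of 20
two-session trials analyzed on ground-truth event times (detector
fidelity is benchmarked separately, so the two error sources are not
conflated); MMD power uses 50 replicates of 200 syllables per side
against a 1-σ mean-pitch shift with a pup-level baseline from an
8-pup cohort. These sizes give tight Monte-Carlo error on every
reported rate while keeping a full validation run in the tens of
seconds on one core.

## Known limitations

- The discontinuity criterion's original units are an interpretation
  (see above); a different definition in legacy tooling would shift
  which borderline frames pass, though merged-syllable output is robust
  to single-frame failures.
- Spectral purity is window-dependent: a Hann window caps single-bin
  purity near 0.6 even for a pure tone, so purity values are comparable
  only within one STFT configuration.
- Onset-based behavior coding and the rate-share normalization are
  conventions; a majority-overlap coding rule is available by
  configuration.
- The optical-flow movement extractor (iterative Lucas–Kanade, summed
  within the body mask; absolute frame-difference fallback) is one of
  several reasonable choices — the downstream covariance contracts are
  deliberately agnostic to it.
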