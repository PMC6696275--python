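# Methods

## The measurement model

Three analog channels are recorded simultaneously while a subject bites
a force meter with the second molar: an earphone-type optical sensor
measuring ear-canal wall movement, the rectified low-pass envelope of
the masseter surface EMG, and the occlusal-force meter output. Each
channel (0–3.3 V) is digitized at 100 Hz with 12-bit resolution and
normalized to the unit interval — the "AD value". One *run* is the 2 s
press window (200 samples) in which the subject ramps from light
contact to maximum pressure; one *session* is K = 6 runs by one
subject.

Force AD values convert to Newtons through the device's affine
calibration `F = 1985.6·ad − 75.066`. The calibration is applied to the
normalized AD value (this reproduces the device's worked conversions,
e.g. 0.6004 → 1117 N) and is deliberately unclamped: AD values below
75.066/1985.6 ≈ 0.0378 map to small negative Newtons, which faithfully
represents an idle channel. `quantize_ad` models the converter as
round-to-nearest over 4095 steps, so both endpoints map exactly and the
quantization error is bounded by half a step.

## Correlation analysis

For each run we compute the three pairwise Pearson coefficients
(ear–force, ear–emg, emg–force) and two first-order partial
correlations: ear–force with the EMG's linear influence removed, and
emg–force with the ear's influence removed, using the standard
recursion

    r_xy.z = (r_xy − r_xz r_yz) / √((1 − r_xz²)(1 − r_yz²)).

The residual-regression form of the same quantity (correlate the
residuals of x|z and y|z) is kept in the test suite as an independent
oracle; the two agree to 1e−10 on random inputs because the identity is
algebraic. Partials are computed per run from that run's own pairwise
coefficients and then summarized across runs — not from run-averaged
coefficients — because each run has its own ear offset and pooling
would mix offsets into the coefficients. Each of the five series is
summarized by its mean and the square root of its unbiased variance
(n−1 denominator). Zero-variance channels and perfectly collinear
controls raise errors rather than producing NaN, since a silent NaN
would corrupt the downstream summaries; `correlation_table` can skip
the partial block (`include_partials=False`) for exactly affine data on
which partials are undefined.

## The anchored single-regression estimator

For fold k of a leave-one-run-out split, every training run i yields
the closed-form OLS slope of force on ear,

    a_ki = (n Σe f − Σe Σf) / (n Σe² − (Σe)²),  n = 200,

and the fold slope is their arithmetic mean ā_k. The held-out run is
predicted anchored at its own first sample:

    f̃_kj = ā_k (e_kj − e_k0) + f_k0.

The fitted intercepts are discarded by construction: the ear channel's
per-run offset drifts between runs while the coupling slope is stable,
so a pooled intercept would be meaningless and the anchor absorbs the
held-out run's offset instead. The anchor is the *first* sample of the
window, matching the intended usage in which the sensor reading at
activation defines the zero-force reference. Estimates are not clamped
to [0, 1] AD; the Newton columns of the reports therefore apply the
affine calibration directly without the measured-value range check.

Per fold we report RMSE_k (AD units), the estimate extrema f̃_kMAX and
f̃_kMIN, their difference (the estimated width) and NRMSE_k = RMSE_k /
width. Per subject, each per-fold column is averaged independently
across folds; consequently the reported mean NRMSE is a mean of ratios
and does not equal mean RMSE divided by mean width (the internal
convention of the standard report layout, which the package
replicates). The fold slopes ā_k are additionally summarized by their
mean ā̄ and n−1 standard deviation. RMSE is computed on the AD scale,
where its magnitude (a few hundredths) is directly comparable across
subjects; Newton-scale columns are available via the calibration.

Degenerate folds (a constant ear channel in any training run) abort the
whole evaluation with the fold and run identity. Skipping such folds
silently would change K and bias every column average.

## Synthetic sessions

Real recordings of this protocol are access restricted, so a seeded
generator produces sessions with the structure the analysis assumes:

* **Latent force ramp** — a smoothstep (3u² − 2u³) rise over the 2 s
  window from a baseline `f_base` to a per-run peak `f_peak·(1 + ε)`,
  ε ~ N(0, peak_jitter). Smoothstep gives the zero-velocity onset and
  plateau of a deliberate press; the relax phase after the press is not
  generated because the analysis uses only the press window.
* **Channels** — all three channels derive from the *same* latent ramp:
  `force = latent + η_f`, `ear = e_base + δ_r + (latent − f_base)/a_s +
  η_e`, `emg = emg_base + g·(latent − f_base) + η_m`, with independent
  Gaussian per-sample noises and a per-run ear offset δ_r ~ N(0,
  drift_sd) drawn once per run. Driving the channels from the latent
  (not from the noisy measured force) is essential: it makes
  force-channel noise leave slope recovery unbiased while ear-channel
  noise produces the classical errors-in-variables attenuation — the
  two behaviours the estimator's evaluation must be able to separate.
* **AD path** — after noise, channels are clamped to [0, 1] and, by
  default, snapped to the 12-bit grid, in that order, matching the
  physical acquisition chain. `quantize=False` gives the ideal path on
  which exactness tests run (quantizing both channels perturbs an
  exactly affine coupling at the ~1e−4 level). Systematic clamping
  (> 5% of samples in a channel) logs a warning, since it means the
  chosen parameters drive the signal off scale.
* **EMG baseline** — `emg_base` keeps the envelope's noise floor above
  the clamp at 0 AD, as a rectified envelope output rests above 0 V; a
  zero baseline would systematically clamp the early, low-force
  samples.

Determinism: a session is a pure function of `(params, K)`; each run
gets an independent child stream spawned from `params.seed`, so
identical inputs give bit-identical sessions at every level.

### Parameter defaults and the preset subjects

Defaults describe a realistic strong-bite subject with negative
coupling: slope a_s = −16.1 AD-force per AD-ear, force range
0.06–0.60 AD (≈ 47–1117 N). The five preset profiles span three
negative and two positive couplings with per-subject slopes between
−22.9 and +18.8 and force ranges between 0.20 and 0.54 AD wide —
magnitudes representative of healthy adults biting a molar force meter.
Noise scales are set relative to each subject's signal excursion
(smoothstep sd ≈ 0.348 × range):

* ear noise = 10% of the ear-signal sd → pairwise ear–force r ≈ 0.99;
* EMG noise = 25% of the EMG-signal sd → emg–force r ≈ 0.97;
* force sensor noise = 5% of the force-signal sd;
* drift_sd = 10% of the ear excursion, giving visibly parallel
  ear–force lines with small offset differences across runs;
* peak jitter 3%, for run-to-run variation in maximal bite force.

The 10%-vs-25% relative-noise ordering is the documented regime in
which the ear channel is the cleaner force proxy for every subject;
under it the ear–force partial correlation (≈ ±0.9) dominates the
emg–force partial correlation (≈ 0.3) in magnitude, which is the
qualitative structure the pipeline is expected to reproduce. These
scales are chosen for structural realism; they are not validated
against any real recording, and absolute correlation or error values on
synthetic sessions characterize the generator, not any device.

### What passing tests show — and what they do not

The generator emulates coupling sign, offset drift, relative channel
SNRs, quantization and clamping. It does not model motion artifacts,
sensor saturation at extreme forces, nonlinear ear-canal mechanics,
EMG-force nonlinearity, or autocorrelated noise. Passing tests
therefore demonstrate that the pipeline's arithmetic and its behaviour
under the assumed noise structure are correct, not that the estimator
achieves any particular accuracy on real ear-canal recordings.

## Numerical choices

* Exactness assertions on the ideal path use absolute tolerance 1e−9;
  the pipeline is floating point, so "exact" means machine precision
  through ~1200-sample computations.
* The slope's degenerate-denominator check tests `ptp(e) == 0` rather
  than comparing the computed denominator to zero, avoiding a
  false-negative from rounding.
* `summarize` returns sd exactly 0 when all values compare equal,
  honouring the "sd = 0 iff all equal" contract that `np.std` alone
  breaks by rounding.
* Session CSVs are read with round-trip float precision so
  write-then-read is the identity.
* Problem sizes in the stochastic tests (100 seeded sessions for slope
  recovery, 10–15 seeds per noise level for monotonicity checks, 1,000
  triples for the partial-correlation oracle) are chosen so Monte-Carlo
  error is well below the asserted margins while the full suite runs in
  seconds.

## Known limitations

* K-fold averaging conventions are replicated as-is; in particular the
  mean-of-ratios NRMSE is not a ratio estimator and has no simple
  variance formula.
* The estimator is a single-channel regression; EMG is analyzed for its
  correlation structure but never enters the prediction.
* With very small ear excursions (|a_s| large relative to the force
  range) the 12-bit grid becomes a visible noise floor on the ear
  channel; the generator warns only about clamping, not about
  quantization-dominated regimes.
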