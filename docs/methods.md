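# Methods

## The measurement

`eyesync` quantifies cross-modal synchronization between scalp EEG and eye
movements during video viewing.  Both modalities are reduced to the same
kind of feature — a *relative band-power trajectory* — and synchronization
between a given eye feature and a given EEG channel is scored as the
held-out R² of a regression predicting the channel's trajectory from the
eye feature's trajectory, band by band.

**Eye features (60 Hz).**  Four per session: fixation distance (Euclidean
displacement between consecutive fixation centroids), saccade amplitude,
and left/right pupil diameter (mean-centered per session).  Fixations and
saccades come from an I-VT classifier: the point-to-point gaze velocity is
compared against a threshold (default 30 deg/s, standard I-VT practice;
fixations shorter than 60 ms between saccades are merged).  Event-valued
features are expanded into dense step-hold series because the sub-Hz
band-pass analysis requires uniform sampling.  Blinks — samples with
non-positive pupil or a failed validity flag — are linearly interpolated
with a 100 ms pad on each side; sessions more than 50% blink are rejected.

**Band-ratio trajectories.**  The EEG (pre-filtered 1–50 Hz) uses
delta 1–4, theta 4–8, alpha 8–13, beta 13–20 Hz; eye features use a
rate-scaled sub-Hz scheme: delta 0.12–0.48, theta 0.48–0.96, alpha
0.96–1.56, beta 1.56–3.6 Hz.  Within each sliding window (180 s long, 1 s
slide in the fidelity profile) a one-sided Hann periodogram with the mean
removed is summed into the four bands (half-open bins `[lo, hi)` so shared
edges are not double-counted), and each band's power is divided by the sum
over the four bands.  The four ratios of every window sum to 1 by
construction; the "total power" denominator is deliberately the four-band
sum, so the ratios live on a simplex (a full-spectrum denominator would
make them depend on out-of-band noise).  Windows are defined in seconds,
so the 60 Hz and 500 Hz streams land on the same 1 s window grid (10 800
eye samples and 90 000 EEG samples per 180 s window); series are paired by
identical window start.  Windows with more than 20% blink-interpolated
samples are excluded.

**Synchronization score.**  For each (eye feature, channel, band, session)
triple the matched band columns are split 7:3 into train and test
windows, a regression is fit on the training part, and the test part is
scored with MAE = (1/m)Σ|h(xᵢ)−yᵢ|, MSE = (1/n)Σ(yᵢ−ŷᵢ)², and
R² = 1 − Σ(yᵢ−ŷᵢ)²/Σ(yᵢ−ȳ)².  Negative R² is reported, never clipped.
Five model families are available with fixed hyperparameters (Bayesian
ridge; OLS; elastic net α=1, l1_ratio=0.5; RBF-SVR C=1, ε=0.1, γ=auto;
gradient boosting with 100 stages, learning rate 0.1, depth 3, squared
error).  Gradient boosting is the default scoring model.

**Split modes — the central validity trade-off.**  Adjacent 180 s windows
at 1 s slide share ~99% of their samples.  A *random* 7:3 split therefore
places near-duplicates of training windows in the test set; scores in
that mode measure how well a model can memorize the session's joint
trajectory and are systematically high and tight.  A *chronological* split
(first 70% of windows train) is leakage-free but leaves a short test
segment whose band-ratio series has only a handful of effectively
independent values, so per-session R² is low-biased and noisy.  Both modes
are implemented; chronological is the library default.  The condition
comparison (below) and the model comparison use the random mode, because
that is the regime the comparison emulates — it is where empathic
sessions separate sharply and reproducibly from non-empathic ones; the
chronological mode backs the null and strength-recovery checks, where
leakage would be disqualifying.

**Condition comparison.**  Per (feature, channel, band, quadrant) cell,
per-session R² values are aggregated to empathic and non-empathic means
with sample standard deviations, compared by a two-tailed Welch t-test,
and filtered by two exclusion rules: a triple is dropped when (1) the
non-empathic mean is at least the empathic mean, or (2) the mean ± 1 std
intervals of the two conditions intersect.  "Std" here is the
between-session standard deviation, not a standard error (a flag switches
to standard errors).  No multiple-testing correction is applied by
default; a Benjamini–Hochberg option exists.  Retained triples are grouped
by valence-arousal quadrant and hemisphere-tagged from the 10-20 channel
name (odd = left, even = right, z = midline; pupil features carry an eye
side, giving same/crossed labels).

## The synthetic cohort generator

There is no public dataset for this design, so the generator is the
ground-truth instrument.  It emulates: 18-channel 500 Hz EEG; a 60 Hz
GazePoint-style gaze/pupil stream with fixational jitter (0.3 deg,
low-passed at 2 Hz so its velocity stays far below the I-VT threshold),
log-normal saccadic jumps (median 3 deg, ~2/s with a 250 ms refractory
floor, reflected inside a ±12 deg screen box), pupils at 3.0 mm baseline
with 0.15 mm-scale fluctuations, and Poisson blinks (12/min, 150 ms,
non-overlapping) that zero the pupils and clear validity flags.  Eight
videos per subject cover the 2×2×2 design: one empathic and one
non-empathic clip per valence-arousal quadrant, 300 s each (video length
is not publicly specified; 300 s comfortably exceeds the 180 s analysis
window).  One RNG stream per (seed, subject, video) makes cohorts
bit-reproducible and safe to generate in parallel.

**Planted coupling.**  A coupling spec names an eye feature, channel, band
and strength in [0, 1].  A shared slow mean-one lognormal envelope e(t) —
a random Fourier series with harmonics below `envelope_hz` (default
0.04 Hz) and log-sd 1.0 — multiplies band-limited unit-variance noise on
both sides: the eye feature receives `strength · e · s` (s band-passed in
the eye band) and the EEG channel receives `strength · e · c` (c
band-passed in the matching EEG band), on top of independent unit-variance
backgrounds scaled by `noise_sd` (default 1.0, putting signal and noise on
equal footing so `strength` acts as a mixing weight).  Both windows' band
shares then rise and fall with e², which is precisely the co-movement the
pipeline measures; at strength 0 the streams are independent.  Fixation
and saccade features are *derived* from events, so their coupling enters
through the log of the scripted jump amplitudes sampled at event times —
band content above half the event rate (~1 Hz) cannot be represented
there, so event-feature couplings are reliable in the eye delta/theta
bands only.  The `monotone_nonlinear` link cubes the eye-side envelope
(rescaled to mean one): eye band power then rises as e⁶ against the EEG
side's e², a monotone but strongly curved power-power relation.  A
pointwise cube of the band-limited source was rejected because it mostly
re-injects a linear in-band component and leaves the measured relation
near-linear.

**What the generator does not emulate.**  No 1/f spectral shaping, volume
conduction, or channel covariance in the EEG; no smooth pursuit,
microsaccades, or stimulus-driven gaze structure; left and right pupils
are independent unless coupled.  Passing tests therefore demonstrate that
the pipeline recovers band-ratio co-movement when it exists and stays
silent when it does not — they do not certify performance on real
recordings, whose artifact structure is richer.

## Verification experiments and problem sizes

The heavy checks run at the package's verification scale: 300 s sessions
(the generator default), 20 s windows with 1 s slide, six-subject cohorts.
The 20 s window keeps enough windows per session for a meaningful
held-out split at this duration; the named `test_profile` configuration
(60 s sessions, 20 s windows) is smaller still and used for smoke tests.

* *Strength recovery*: with a coupling planted at strengths {0, 0.25,
  0.5, 0.75, 0.95}, the planted triple's mean chronological-split R²
  (six subjects, five seeds per strength) is monotone in strength
  (Spearman ρ = 1.0 in the shipped runs, rising from well below zero to
  about +0.6);
  fully uncoupled cohorts stay far below zero on average.
* *Condition discrimination*: coupling planted at 0.95 only in empathic
  sessions; per quadrant, six empathic vs six non-empathic session scores
  (random split).  The planted triple passes both exclusion rules with
  p < 10⁻³ in essentially every (seed, quadrant) instance, while a fixed
  panel of seven uncoupled triples is retained at a rate well under 0.1.
* *Model comparison*: run on monotone-nonlinear coupled data at the
  fidelity window (180 s) with a slower whole-session drift envelope
  (`envelope_hz` 0.02), emulating features that converge gradually over a
  viewing.  In this near-duplicate-window regime the boosted-tree model
  memorizes the nonlinear trajectory (mean R² ≈ 0.99) and clearly beats
  the linear models (≈ 0.87), with SVR mid-pack and elastic net at ≈ 0 —
  elastic net's unit penalty flattens the tiny-variance ratio features to
  a constant.  With stationary envelopes and leakage-free splits the
  boosted model's variance cost cancels its flexibility on these 1-D
  features and the two families tie; the ranking is a property of the
  overlapping-window regime, not of the estimator in general.

## Numerical choices and edge cases

* Filters: 4th-order Butterworth, applied forward-backward
  (`sosfiltfilt`), for analysis band-passing and the 1–50 Hz EEG
  pre-filter.
* Latent-source synthesis: the generator's band-limited sources are made
  by Fourier masking of white noise (exactly in-band); recursive filters
  leave edge transients and low-side leakage that are severe for sub-Hz
  bands at 60 Hz.  The slow envelope is a random Fourier series over the
  harmonics below its cutoff, for the same reason.
* Periodograms: Hann taper, constant detrend, one-sided, `density`
  scaling; the sliding computation uses a spectrogram with hop =
  slide × rate and is bin-identical to a per-window periodogram (tested).
* All-zero windows: band ratios undefined; the window is flagged and
  excluded from pairing rather than NaN-propagated.
* Zero-variance test targets: R² undefined; the result is flagged
  (`undefined=True`), not raised, inside the 288-triple matrix.
* Degenerate t-test (both groups constant and equal): t = 0, p = 1.
* Model-selection ties: highest R², then lowest MSE, then a fixed model
  order.
* EDF export quantizes to 16 bits over each channel's physical range;
  flat channels are given a unit range to avoid zero gain.  Reading EDF
  goes through `mne`, which independently validates the writer.

## Known limitations

* The chronological split's short test segment makes single-session R²
  noisy at desk scale; condition-level conclusions should always pool
  sessions.
* Event-derived features cannot carry planted coupling above ~1 Hz.
* The fixation-distance definition follows the stated intent
  (displacement between consecutive centroids); the literal combined-norm
  variant is available via `literal_norm=True` for comparability.
* Real-data idiosyncrasies — drift between device clocks, partial blinks,
  smooth pursuit — are out of scope of the generator and untested here.
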