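# eyesync

Synchronization analysis between EEG band-power ratios and eye-movement
features during video viewing, with a verifiable synthetic-data path.

## The problem

When a viewer empathizes with emotional video content, do their eye
movements co-vary with their brain activity?  One way to ask this
quantitatively: reduce both an EEG channel and an eye-movement feature
(pupil diameter, fixation distance, saccade amplitude) to *relative
band-power trajectories* — per sliding window, the fraction of power in
each of four frequency bands — and score how well a regression predicts
the EEG trajectory from the eye trajectory on held-out windows.  The test
R² is the synchronization score:

    ratio_b(t) = P_b(t) / Σ_b' P_b'(t)          (per window t, band b)
    R² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²           (held-out windows)

EEG uses the conventional delta/theta/alpha/beta edges (1–20 Hz); eye
features use a rate-scaled sub-Hz scheme (0.12–3.6 Hz).  Windows are long
(180 s, sliding by 1 s in the fidelity profile) and the 60 Hz gaze and
500 Hz EEG streams are aligned on the same 1 s window grid.  Per-session
scores for each (eye feature × 18 channels × 4 bands) triple are then
aggregated by condition: empathic vs non-empathic viewings are compared
per valence-arousal quadrant with a Welch t-test, and triples where
empathy confers no advantage (non-empathic mean at least as high, or
mean ± std intervals overlapping) are excluded.

No public dataset accompanies this design, so the package ships a
first-class synthetic-data module: coupled EEG + gaze cohorts in which a
shared slow envelope modulates band-limited sources on both sides with a
known strength, giving ground truth against which the entire pipeline is
verified (blink recovery, I-VT event recovery, band-ratio normalization,
coupling-strength monotonicity, condition discrimination).

Audience: researchers in affective computing / multimodal physiology who
want a tested, reproducible reference implementation of this kind of
cross-modal coupling analysis, or a harness for method development
against known ground truth.

## Worked example

```python
from eyesync import (CouplingSpec, RegressionSpec, RunConfig,
                     SyntheticConfig, align_ratio_series, fit_sync,
                     generate_session, process_session)

synth = SyntheticConfig(
    n_subjects=1, n_videos=1, duration_s=300.0, seed=8,
    couplings=(CouplingSpec("pupil_right", "F3", "delta", strength=0.95),))
cfg = RunConfig(synthetic=synth, window_s=20.0)

session = generate_session(synth, subject_id=0, video_id=0)
eye, eeg = process_session(session.eeg, session.gaze, cfg,
                           channels=["F3"], features=["pupil_right"])
_, xr, yr = align_ratio_series(eye["pupil_right"], eeg["F3"])
res = fit_sync(xr[:, 0], yr[:, 0], RegressionSpec(model="gbr", seed=0))
print(f"R2 {res.r2:+.3f}  MAE {res.mae:.4f}  "
      f"({res.n_train} train / {res.n_test} test windows)")
```

Output:

```
R2 +0.660  MAE 0.0937  (196 train / 85 test windows)
```

The planted right-pupil ↔ F3 delta coupling at strength 0.95 yields a
held-out R² of about +0.6 under the leakage-free chronological split —
far above the uncoupled baseline, which averages well below zero at this
problem size (the same pair in an uncoupled cohort is indistinguishable
from noise).  `examples/` walks through each capability: cohort
synthesis, eye features, band ratios, synchronization scoring and model
comparison, condition comparison, and the end-to-end pipeline; each
script prints the numbers it computes and what they mean.

A thin CLI wraps the pipeline for shell use:

```bash
eyesync synth --n-subjects 2 --duration-s 60 --outdir cohort --seed 1
eyesync run-all --outdir run1 --seed 1
eyesync report --outdir run1
```

## Layout

```
src/eyesync/
  montage.py      # 10-20 channel set, hemisphere parity
  io.py           # EEG/gaze containers, CSV + EDF round trips
  synthetic.py    # coupled cohort generator (ground truth)
  eye_features.py # blink removal, I-VT, feature series
  spectral.py     # band schemes, periodogram band ratios, sliding windows
  sync.py         # metrics, splits, five models, 288-triple matrix
  comparison.py   # Welch tests, exclusion rules, quadrant report
  experiments.py  # planted-coupling verification experiments
  pipeline.py     # RunConfig, run_all, artifacts, provenance
  cli.py          # thin click wrapper
docs/methods.md   # models, assumptions, parameter rationale, limitations
examples/         # one narrative script per capability
```
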