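"""Synthetic coupled EEG + gaze cohorts with known ground truth.

The study design being emulated: each subject watches eight videos, one
empathic and one non-empathic per valence-arousal quadrant, while 18-channel
EEG (500 Hz) and GazePoint-style gaze/pupil streams (60 Hz) are recorded.
No real data accompanies the analysis, so this module manufactures sessions
in which the *windowed band-ratio coupling* the pipeline measures is planted
with a known strength.

Coupling mechanism.  Each :class:`CouplingSpec` names an eye feature, an
EEG channel and a band.  A shared slow mean-one lognormal envelope ``e(t)``
(low-pass filtered white noise) modulates band-limited unit-variance
sources on both sides:

* eye side: ``strength * g(e(t)) * s(t)`` is added to the feature's
  generative trace, where ``s`` is band-passed white noise in the eye-band
  edges and ``g`` is the identity (``link="linear"``) or a mean-one rescaled
  cube (``link="monotone_nonlinear"``: windowed eye band power then rises as
  the cube of the EEG side's, a monotone but strongly curved relation);
* EEG side: ``strength * e(t) * c(t)`` is added to the channel, where ``c``
  is band-passed white noise inside the matching EEG band.

Because both injections ride the same envelope, the windowed relative power
of that band rises and falls together in the two modalities, which is
exactly the co-movement the downstream regression is asked to recover; with
``strength = 0`` the two streams are independent.

Fixation/saccade features cannot be written into the gaze trace directly
(they are *derived* from events), so their coupling enters through the log
amplitude of the scripted gaze jumps, sampled at event times.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import EEGRecording, GazeRecording, SessionLabel, write_eeg, write_gaze
from .montage import CHANNELS
from .spectral import EEG_SCHEME, EYE_SCHEME, BAND_NAMES
from .eye_features import EYE_FEATURES

_QUADRANT_ORDER = (
    ("pleasant", "aroused"),
    ("pleasant", "relaxed"),
    ("unpleasant", "relaxed"),
    ("unpleasant", "aroused"),
)


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling between one eye feature and one EEG band.

    ``strength`` in [0, 1] is the mixing weight of the shared latent source
    relative to unit-variance background noise.  ``empathic`` / ``quadrant``
    optionally restrict the coupling to matching sessions (None = all).
    """

    eye_feature: str
    channel: str
    band: str
    strength: float
    link: str = "linear"  # linear | monotone_nonlinear
    empathic: bool | None = None
    quadrant: str | None = None

    def __post_init__(self) -> None:
        if self.eye_feature not in EYE_FEATURES:
            raise ValueError(f"unknown eye feature {self.eye_feature!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        if self.link not in ("linear", "monotone_nonlinear"):
            raise ValueError(f"unknown link {self.link!r}")

    def applies_to(self, label: SessionLabel) -> bool:
        if self.empathic is not None and self.empathic != label.empathic:
            return False
        if self.quadrant is not None and self.quadrant != label.quadrant:
            return False
        return True


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters.

    Defaults mirror the emulated study where it states values (8 videos
    covering the four quadrants in empathic/non-empathic pairs, 500 Hz EEG,
    60 Hz gaze); free parameters (noise, blink and saccade rates, stimulus
    duration) are fixed at values documented in the methods note.
    """

    n_subjects: int
    n_videos: int = 8
    duration_s: float = 300.0
    eeg_rate: float = 500.0
    gaze_rate: float = 60.0
    couplings: tuple[CouplingSpec, ...] = ()
    noise_sd: float = 1.0
    blink_rate_per_min: float = 12.0
    blink_duration_ms: float = 150.0
    saccade_rate_per_s: float = 2.0
    envelope_hz: float = 0.04    # bandwidth of the shared slow envelope
    envelope_log_sd: float = 1.0  # log-sd of the lognormal envelope
    jitter_deg: float = 0.3      # fixational jitter sd around centers
    jump_scale_deg: float = 3.0  # median saccade amplitude
    pupil_baseline_mm: float = 3.0
    pupil_scale_mm: float = 0.15
    condition_labels: tuple[tuple[bool, str, str], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_videos <= 0:
            raise ValueError("n_subjects and n_videos must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("eeg_rate", "gaze_rate", "blink_rate_per_min",
                     "saccade_rate_per_s"):
            if getattr(self, name) < 0 or (name.endswith("rate") and
                                           getattr(self, name) <= 0):
                raise ValueError(f"{name} must be non-negative")
        self.couplings = tuple(self.couplings)

    def label_for(self, subject_id: int, video_id: int) -> SessionLabel:
        if self.condition_labels is not None:
            empathic, valence, arousal = self.condition_labels[
                video_id % len(self.condition_labels)]
        else:
            valence, arousal = _QUADRANT_ORDER[(video_id // 2) % 4]
            empathic = video_id % 2 == 0
        return SessionLabel(empathic=empathic, valence=valence,
                            arousal=arousal, subject_id=subject_id,
                            video_id=video_id)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["couplings"] = [asdict(c) for c in self.couplings]
        return d


@dataclass
class SessionTruth:
    """Ground truth recorded alongside a generated session."""

    blink_intervals: list[tuple[float, float]] = field(default_factory=list)
    jump_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    jump_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    couplings: tuple[CouplingSpec, ...] = ()


@dataclass
class SyntheticSession:
    eeg: EEGRecording
    gaze: GazeRecording
    label: SessionLabel
    truth: SessionTruth

    def __iter__(self):  # tuple-style unpacking (eeg, gaze, label)
        return iter((self.eeg, self.gaze, self.label))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def bandlimited_noise(n: int, rate: float, f_lo: float, f_hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise exactly band-limited to [f_lo, f_hi).

    Synthesized by Fourier masking of white noise: zero-phase band-passing
    with a recursive filter leaves edge transients and slow-rolloff leakage
    that are severe for sub-Hz bands at 60 Hz, whereas the spectral mask
    places all power strictly inside the band.
    """
    spectrum = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spectrum[(freqs < f_lo) | (freqs >= f_hi)] = 0.0
    x = np.fft.irfft(spectrum, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_envelope(n: int, rate: float, cutoff_hz: float,
                   rng: np.random.Generator, sigma: float = 0.6) -> np.ndarray:
    """Mean-one lognormal envelope varying on the 1/cutoff_hz timescale.

    Built from a random Fourier series over the harmonics below the cutoff
    so the process is exactly band-limited and free of filter edge
    transients; ``z`` is unit-variance by construction.
    """
    t = np.arange(n) / rate
    duration = n / rate
    k_max = max(1, int(np.floor(cutoff_hz * duration)))
    freqs = np.arange(1, k_max + 1) / duration
    a = rng.standard_normal(k_max)
    b = rng.standard_normal(k_max)
    phase = 2 * np.pi * freqs[:, None] * t[None, :]
    z = (a @ np.cos(phase) + b @ np.sin(phase)) / np.sqrt(k_max)
    return np.exp(sigma * z - sigma ** 2 / 2)


def _session_rng(seed: int, subject_id: int, video_id: int
                 ) -> np.random.Generator:
    # one stream per session so cohorts reproduce under parallel generation
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(subject_id, video_id))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# blink injection
# ---------------------------------------------------------------------------

def inject_blinks(gaze: GazeRecording, rate_per_min: float,
                  duration_ms: float,
                  rng: np.random.Generator | int | None = None,
                  ) -> tuple[GazeRecording, list[tuple[float, float]]]:
    """Zero out pupils and clear validity in Poisson-placed blink intervals.

    The number of blinks is Poisson with mean ``rate_per_min`` per minute;
    intervals of fixed ``duration_ms`` are placed uniformly with overlap
    rejection.  Returns the modified copy and the ground-truth intervals.
    """
    if rate_per_min < 0 or duration_ms <= 0:
        raise ValueError("blink rate must be >= 0 and duration positive")
    if rate_per_min == 0:
        return gaze.copy(), []
    if duration_ms / 1000.0 >= gaze.duration:
        raise ValueError("blink duration exceeds recording length")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dur_s = duration_ms / 1000.0
    n_blinks = rng.poisson(rate_per_min * gaze.duration / 60.0)
    t0 = gaze.time[0]
    out = gaze.copy()
    intervals: list[tuple[float, float]] = []
    attempts = 0
    while len(intervals) < n_blinks and attempts < 100 * max(n_blinks, 1):
        attempts += 1
        start = t0 + rng.uniform(0, gaze.duration - dur_s)
        end = start + dur_s
        if any(start < e + dur_s and end > s - dur_s for s, e in intervals):
            continue  # reject overlaps (with a one-blink guard gap)
        intervals.append((start, end))
    intervals.sort()
    for start, end in intervals:
        sel = (gaze.time >= start) & (gaze.time < end)
        out.pupil_left[sel] = 0.0
        out.pupil_right[sel] = 0.0
        out.valid_left[sel] = False
        out.valid_right[sel] = False
    return out, intervals


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def generate_session(config: SyntheticConfig, subject_id: int,
                     video_id: int) -> SyntheticSession:
    """Generate one coupled EEG + gaze session.

    Deterministic: identical (config, subject_id, video_id) yields
    bit-identical signals.  Random draws do not depend on coupling
    strengths, so strength sweeps under one seed are sample-paired.
    """
    label = config.label_for(subject_id, video_id)
    rng = _session_rng(config.seed, subject_id, video_id)
    n_gaze = int(round(config.duration_s * config.gaze_rate))
    n_eeg = int(round(config.duration_s * config.eeg_rate))
    t60 = np.arange(n_gaze) / config.gaze_rate
    t500 = np.arange(n_eeg) / config.eeg_rate

    active = tuple(c for c in config.couplings if c.applies_to(label))

    # latent sources: one envelope + eye-band source per coupling, drawn
    # unconditionally on strength
    eye_inj = {f: np.zeros(n_gaze) for f in EYE_FEATURES}
    eeg_inj: list[tuple[str, np.ndarray]] = []
    for c in active:
        env60 = _slow_envelope(n_gaze, config.gaze_rate, config.envelope_hz,
                               rng, sigma=config.envelope_log_sd)
        lo, hi = EYE_SCHEME.edges(c.band)
        s60 = bandlimited_noise(n_gaze, config.gaze_rate, lo, hi, rng)
        if c.link == "monotone_nonlinear":
            # cube the eye-side envelope (rescaled to mean one): windowed eye
            # band power then goes as e^6 against the EEG side's e^2, a
            # monotone but strongly curved power-power relation
            env_eye = env60 ** 3
            env_eye = env_eye / env_eye.mean()
        else:
            env_eye = env60
        x = env_eye * s60
        eye_inj[c.eye_feature] = eye_inj[c.eye_feature] + c.strength * x

        env500 = np.interp(t500, t60, env60)
        elo, ehi = EEG_SCHEME.edges(c.band)
        carrier = bandlimited_noise(n_eeg, config.eeg_rate, elo, ehi, rng)
        eeg_inj.append((c.channel, c.strength * env500 * carrier))

    gaze, truth = _generate_gaze(config, rng, t60, eye_inj)
    truth.couplings = active

    # EEG: independent broadband background per channel plus injections
    data = np.empty((len(CHANNELS), n_eeg))
    for i in range(len(CHANNELS)):
        data[i] = config.noise_sd * bandlimited_noise(
            n_eeg, config.eeg_rate, 1.0, 45.0, rng)
    for channel, inj in eeg_inj:
        data[CHANNELS.index(channel)] += inj
    eeg = EEGRecording(rate=config.eeg_rate, channels=list(CHANNELS),
                       data=data)

    if config.blink_rate_per_min > 0:
        gaze, intervals = inject_blinks(
            gaze, config.blink_rate_per_min, config.blink_duration_ms, rng)
        truth.blink_intervals = intervals

    return SyntheticSession(eeg=eeg, gaze=gaze, label=label, truth=truth)


def _generate_gaze(config: SyntheticConfig, rng: np.random.Generator,
                   t60: np.ndarray, eye_inj: dict[str, np.ndarray],
                   ) -> tuple[GazeRecording, SessionTruth]:
    n = len(t60)
    rate = config.gaze_rate

    # scripted jump times: exponential gaps with a floor so fixations stay
    # classifiable (>= 250 ms)
    mean_gap = 1.0 / config.saccade_rate_per_s
    gaps = 0.25 + rng.exponential(max(mean_gap - 0.25, 1e-3),
                                  size=int(config.duration_s
                                           * config.saccade_rate_per_s * 3))
    jump_times = 0.5 + np.cumsum(gaps)
    jump_times = jump_times[jump_times < config.duration_s - 0.25]

    # jump amplitudes: log-normal, log-mean shifted by the event-feature
    # injection sampled at the jump time
    evt_idx = np.clip((jump_times * rate).round().astype(int), 0, n - 1)
    evt_drive = (eye_inj["fixation_distance"][evt_idx]
                 + eye_inj["saccade_amplitude"][evt_idx])
    log_amp = (np.log(config.jump_scale_deg)
               + 0.4 * (evt_drive
                        + config.noise_sd * rng.standard_normal(len(evt_idx))))
    amplitudes = np.clip(np.exp(log_amp), 0.3, 15.0)

    # fixation centers: random-walk with reflection inside a +/-12 deg box
    angles = rng.uniform(0, 2 * np.pi, size=len(evt_idx))
    cx = np.zeros(n)
    cy = np.zeros(n)
    px, py = 0.0, 0.0
    prev = 0
    for k, idx in enumerate(evt_idx):
        cx[prev:idx] = px
        cy[prev:idx] = py
        px = _reflect(px + amplitudes[k] * np.cos(angles[k]), 12.0)
        py = _reflect(py + amplitudes[k] * np.sin(angles[k]), 12.0)
        prev = idx
    cx[prev:] = px
    cy[prev:] = py

    # fixational jitter: low-passed white noise rescaled to jitter_deg so
    # point-to-point velocity stays well under the I-VT threshold
    jx = _smooth_jitter(n, rate, config.jitter_deg, rng)
    jy = _smooth_jitter(n, rate, config.jitter_deg, rng)

    bg_left = bandlimited_noise(n, rate, 0.05, 5.0, rng)
    bg_right = bandlimited_noise(n, rate, 0.05, 5.0, rng)
    # floored above zero so extreme excursions are not mistaken for blinks
    pupil_left = np.maximum(
        config.pupil_baseline_mm + config.pupil_scale_mm
        * (eye_inj["pupil_left"] + config.noise_sd * bg_left), 0.2)
    pupil_right = np.maximum(
        config.pupil_baseline_mm + config.pupil_scale_mm
        * (eye_inj["pupil_right"] + config.noise_sd * bg_right), 0.2)

    gaze = GazeRecording(
        rate=rate, time=t60, gaze_x=cx + jx, gaze_y=cy + jy,
        pupil_left=pupil_left, pupil_right=pupil_right,
        valid_left=np.ones(n, dtype=bool),
        valid_right=np.ones(n, dtype=bool))
    truth = SessionTruth(jump_times=jump_times, jump_amplitudes=amplitudes)
    return gaze, truth


def _reflect(x: float, bound: float) -> float:
    if x > bound:
        return 2 * bound - x
    if x < -bound:
        return -2 * bound - x
    return x


def _smooth_jitter(n: int, rate: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(2, 2.0, btype="low", fs=rate, output="sos")
    j = sps.sosfiltfilt(sos, rng.standard_normal(n))
    s = j.std()
    return j / s * sd if s > 0 else j


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def iter_sessions(config: SyntheticConfig):
    """Yield every (subject, video) session of the cohort, in order."""
    for subject_id in range(config.n_subjects):
        for video_id in range(config.n_videos):
            yield generate_session(config, subject_id, video_id)


def generate_cohort(config: SyntheticConfig, outdir: str | Path,
                    write_edf: bool = False) -> dict:
    """Write the cohort to disk and return the manifest.

    Layout: ``<outdir>/subject_<k>/video_<j>_eeg.csv`` (+ optional
    ``.edf``), ``..._gaze.csv`` and a top-level ``manifest.json`` recording
    labels, ground-truth couplings and blink intervals.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sessions = []
    for session in iter_sessions(config):
        lab = session.label
        subj_dir = outdir / f"subject_{lab.subject_id}"
        subj_dir.mkdir(exist_ok=True)
        eeg_path = subj_dir / f"video_{lab.video_id}_eeg.csv"
        gaze_path = subj_dir / f"video_{lab.video_id}_gaze.csv"
        write_eeg(session.eeg, eeg_path)
        write_gaze(session.gaze, gaze_path)
        entry = {
            "subject_id": lab.subject_id,
            "video_id": lab.video_id,
            "empathic": lab.empathic,
            "valence": lab.valence,
            "arousal": lab.arousal,
            "eeg_path": str(eeg_path.relative_to(outdir)),
            "gaze_path": str(gaze_path.relative_to(outdir)),
            "blink_intervals": [list(map(float, iv))
                                for iv in session.truth.blink_intervals],
            "couplings": [asdict(c) for c in session.truth.couplings],
        }
        if write_edf:
            edf_path = subj_dir / f"video_{lab.video_id}_eeg.edf"
            write_eeg(session.eeg, edf_path, format="edf")
            entry["eeg_edf_path"] = str(edf_path.relative_to(outdir))
        sessions.append(entry)
    manifest = {"config": config.to_dict(), "sessions": sessions}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["checksum"] = hashlib.sha256(
        manifest_path.read_bytes()).hexdigest()
    return manifest
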