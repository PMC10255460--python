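"""Eye-movement feature extraction at 60 Hz.

Produces the four feature series the synchronization analysis consumes:
fixation distance (displacement between consecutive fixation centroids),
saccade amplitude, and left/right pupil diameter.  Blinks are removed by
linear interpolation before event classification; fixations and saccades
come from a velocity-threshold (I-VT) classifier.

Event-level values (one number per fixation pair or saccade) are expanded
into dense 60 Hz step-hold series so they can be band-pass analyzed in the
sub-Hz eye band scheme, which requires uniform sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GazeRecording

logger = logging.getLogger(__name__)

EYE_FEATURES = ("fixation_distance", "saccade_amplitude",
                "pupil_left", "pupil_right")

#: Lateral side of each eye feature for hemisphere tagging (None = unsided).
FEATURE_SIDE = {
    "fixation_distance": None,
    "saccade_amplitude": None,
    "pupil_left": "left",
    "pupil_right": "right",
}


@dataclass
class EyeFeatureSeries:
    """One dense 60 Hz eye-feature trace plus its blink-interpolation mask."""

    feature: str
    rate: float
    values: np.ndarray
    blink_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.blink_mask = np.asarray(self.blink_mask, dtype=bool)
        if self.feature not in EYE_FEATURES:
            raise ValueError(f"unknown eye feature {self.feature!r}")
        if len(self.values) != len(self.blink_mask):
            raise ValueError("values and blink_mask lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite after cleaning")


@dataclass
class GazeEvent:
    """A fixation or saccade segment from I-VT classification."""

    kind: str  # "fixation" | "saccade"
    start_s: float
    end_s: float
    centroid_x: float = np.nan
    centroid_y: float = np.nan
    amplitude: float = np.nan
    peak_velocity: float = np.nan

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def velocity(self) -> float:
        """Mean velocity of a saccade: amplitude / duration."""
        return self.amplitude / self.duration


# ---------------------------------------------------------------------------
# Blink removal
# ---------------------------------------------------------------------------

def remove_blinks(gaze: GazeRecording, pad_ms: float = 100.0,
                  max_blink_frac: float = 0.5,
                  ) -> tuple[GazeRecording, np.ndarray, list[tuple[float, float]]]:
    """Interpolate blink samples in pupil and gaze traces.

    Samples where either eye reports pupil <= 0 or an invalid flag form the
    detected blink cores; the returned intervals cover those cores.  The
    interpolation additionally pads each core by ``pad_ms`` per side to
    absorb partial-occlusion tails, and the returned boolean mask marks
    every interpolated sample.

    Raises ``ValueError`` when blinks cover more than ``max_blink_frac`` of
    the recording (unusable session).
    """
    core = (
        (gaze.pupil_left <= 0) | (gaze.pupil_right <= 0)
        | ~gaze.valid_left | ~gaze.valid_right
    )
    intervals = [(gaze.time[s], gaze.time[e - 1] + 1.0 / gaze.rate)
                 for s, e in _runs(core)]

    pad = int(round(pad_ms / 1000.0 * gaze.rate))
    mask = core.copy()
    for s, e in _runs(core):
        mask[max(0, s - pad):min(len(mask), e + pad)] = True

    if mask.mean() > max_blink_frac:
        raise ValueError(
            f"blinks cover {mask.mean():.0%} of the recording "
            f"(> {max_blink_frac:.0%}): unusable session")

    clean = gaze.copy()
    for attr in ("pupil_left", "pupil_right", "gaze_x", "gaze_y"):
        setattr(clean, attr, _interpolate(gaze.time, getattr(gaze, attr), mask))
    clean.valid_left = np.ones(gaze.n_samples, dtype=bool)
    clean.valid_right = np.ones(gaze.n_samples, dtype=bool)
    return clean, mask, intervals


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _interpolate(time: np.ndarray, values: np.ndarray,
                 mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return values.copy()
    good = ~mask
    if not good.any():
        raise ValueError("no valid samples to interpolate from")
    return np.interp(time, time[good], values[good])


# ---------------------------------------------------------------------------
# I-VT classification
# ---------------------------------------------------------------------------

def classify_ivt(gaze: GazeRecording, velocity_threshold: float = 30.0,
                 min_fixation_ms: float = 60.0) -> list[GazeEvent]:
    """Velocity-threshold identification of fixations and saccades.

    Point-to-point velocity is computed from consecutive gaze samples
    (units of gaze coordinates per second).  Runs of samples whose velocity
    exceeds the threshold become saccades; everything else is fixation.
    Fixations shorter than ``min_fixation_ms`` squeezed between saccades
    are merged into the surrounding saccade.  The returned events partition
    the recording timeline.
    """
    if velocity_threshold <= 0:
        raise ValueError("velocity threshold must be positive")
    x, y, t = gaze.gaze_x, gaze.gaze_y, gaze.time
    n = gaze.n_samples
    step = np.hypot(np.diff(x), np.diff(y))
    vel = np.zeros(n)
    vel[1:] = step / np.diff(t)  # sample i: velocity over (i-1, i]

    is_sac = vel > velocity_threshold
    is_sac[0] = False

    # merge too-short fixations flanked by saccades into one saccade
    min_fix = int(round(min_fixation_ms / 1000.0 * gaze.rate))
    runs = _segment(is_sac)
    merged = True
    while merged:
        merged = False
        for i, (kind, s, e) in enumerate(runs):
            if (kind == "fixation" and (e - s) < min_fix
                    and 0 < i < len(runs) - 1):
                runs = (runs[:i - 1]
                        + [("saccade", runs[i - 1][1], runs[i + 1][2])]
                        + runs[i + 2:])
                merged = True
                break

    events: list[GazeEvent] = []
    dt = 1.0 / gaze.rate
    for kind, s, e in runs:
        start_s = float(t[s])
        end_s = float(t[e - 1] + dt)
        if kind == "fixation":
            events.append(GazeEvent(
                kind="fixation", start_s=start_s, end_s=end_s,
                centroid_x=float(x[s:e].mean()),
                centroid_y=float(y[s:e].mean())))
        else:
            pre = max(s - 1, 0)
            post = min(e, n) - 1
            amp = float(np.hypot(x[post] - x[pre], y[post] - y[pre]))
            events.append(GazeEvent(
                kind="saccade", start_s=start_s, end_s=end_s,
                amplitude=amp, peak_velocity=float(vel[s:e].max())))
    return events


def _segment(is_sac: np.ndarray) -> list[tuple[str, int, int]]:
    segs: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(is_sac) + 1):
        if i == len(is_sac) or is_sac[i] != is_sac[start]:
            segs.append(("saccade" if is_sac[start] else "fixation", start, i))
            start = i
    return segs


def events_to_frame(events: list[GazeEvent]):
    import pandas as pd

    return pd.DataFrame(
        [(e.kind, e.start_s, e.end_s, e.centroid_x, e.centroid_y,
          e.amplitude, e.peak_velocity) for e in events],
        columns=["kind", "start_s", "end_s", "centroid_x", "centroid_y",
                 "amplitude", "peak_velocity"])


# ---------------------------------------------------------------------------
# Feature series
# ---------------------------------------------------------------------------

def _sample_index(t_s: float, t0: float, rate: float, n: int) -> int:
    return int(np.clip(round((t_s - t0) * rate), 0, n))


def fixation_distance_series(events: list[GazeEvent], rate: float,
                             n_samples: int, t0: float = 0.0,
                             blink_mask: np.ndarray | None = None,
                             literal_norm: bool = False) -> EyeFeatureSeries:
    """Step-hold series of distances between consecutive fixation centroids.

    During fixation k (k >= 1) the series holds the Euclidean distance
    between centroids k-1 and k; saccade samples hold the previous value
    and the series is 0 before the second fixation.  ``literal_norm``
    switches to the combined norm sqrt(|A|^2 + |B|^2) of the two centroid
    vectors instead of their separation (compatibility variant).
    """
    fixes = [e for e in events if e.kind == "fixation"]
    values = np.zeros(n_samples)
    if len(fixes) < 2:
        logger.warning("fewer than 2 fixations: fixation-distance series "
                       "is all zeros")
    else:
        for prev, cur in zip(fixes[:-1], fixes[1:]):
            if literal_norm:
                d = float(np.sqrt(prev.centroid_x ** 2 + prev.centroid_y ** 2
                                  + cur.centroid_x ** 2 + cur.centroid_y ** 2))
            else:
                d = float(np.hypot(cur.centroid_x - prev.centroid_x,
                                   cur.centroid_y - prev.centroid_y))
            values[_sample_index(cur.start_s, t0, rate, n_samples):] = d
    mask = (np.zeros(n_samples, dtype=bool) if blink_mask is None
            else blink_mask)
    return EyeFeatureSeries("fixation_distance", rate, values, mask)


def saccade_amplitude_series(events: list[GazeEvent], rate: float,
                             n_samples: int, t0: float = 0.0,
                             blink_mask: np.ndarray | None = None,
                             use_velocity: bool = False) -> EyeFeatureSeries:
    """60 Hz series equal to saccade amplitude during each saccade, else 0.

    ``use_velocity`` substitutes the event's mean velocity
    (amplitude / duration) for its amplitude.
    """
    values = np.zeros(n_samples)
    for e in events:
        if e.kind != "saccade":
            continue
        s = _sample_index(e.start_s, t0, rate, n_samples)
        stop = _sample_index(e.end_s, t0, rate, n_samples)
        values[s:stop] = e.velocity if use_velocity else e.amplitude
    mask = (np.zeros(n_samples, dtype=bool) if blink_mask is None
            else blink_mask)
    return EyeFeatureSeries("saccade_amplitude", rate, values, mask)


def pupil_series(gaze: GazeRecording, side: str,
                 blink_mask: np.ndarray | None = None) -> EyeFeatureSeries:
    """Cleaned pupil diameter for one eye, mean-centered per session."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    raw = gaze.pupil_left if side == "left" else gaze.pupil_right
    values = raw - raw.mean()
    mask = (np.zeros(gaze.n_samples, dtype=bool) if blink_mask is None
            else blink_mask)
    return EyeFeatureSeries(f"pupil_{side}", gaze.rate, values, mask)


def extract_features(gaze: GazeRecording, velocity_threshold: float = 30.0,
                     min_fixation_ms: float = 60.0, pad_ms: float = 100.0,
                     ) -> dict[str, EyeFeatureSeries]:
    """Full eye-feature extraction: blink removal, I-VT, four series."""
    clean, mask, _ = remove_blinks(gaze, pad_ms=pad_ms)
    events = classify_ivt(clean, velocity_threshold=velocity_threshold,
                          min_fixation_ms=min_fixation_ms)
    n = clean.n_samples
    t0 = float(clean.time[0])
    return {
        "fixation_distance": fixation_distance_series(
            events, clean.rate, n, t0, blink_mask=mask),
        "saccade_amplitude": saccade_amplitude_series(
            events, clean.rate, n, t0, blink_mask=mask),
        "pupil_left": pupil_series(clean, "left", blink_mask=mask),
        "pupil_right": pupil_series(clean, "right", blink_mask=mask),
    }
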