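"""Shared builders for synthetic gaze traces used across test modules."""

import numpy as np

from eyesync import GazeRecording


def make_gaze(x, y, pupil=3.0, rate=60.0):
    n = len(x)
    p = np.full(n, pupil) if np.isscalar(pupil) else np.asarray(pupil, float)
    return GazeRecording(rate=rate, time=np.arange(n) / rate,
                         gaze_x=np.asarray(x, float),
                         gaze_y=np.asarray(y, float),
                         pupil_left=p.copy(), pupil_right=p.copy(),
                         valid_left=np.ones(n, bool),
                         valid_right=np.ones(n, bool))


def scripted_jump_gaze(n_jumps=20, rate=60.0, duration=60.0, jump=5.0,
                       jitter=0.0, seed=0):
    """Piecewise-constant gaze with evenly spaced instantaneous jumps."""
    n = int(duration * rate)
    x = np.zeros(n)
    rng = np.random.default_rng(seed)
    jump_idx = np.linspace(n // 10, n - n // 10, n_jumps).astype(int)
    pos = 0.0
    prev = 0
    count = 0
    for idx in jump_idx:
        x[prev:idx] = pos
        count += 1
        pos += jump * (1 if count % 2 else -1)
        prev = idx
    x[prev:] = pos
    if jitter:
        x = x + jitter * rng.standard_normal(n)
    return make_gaze(x, np.zeros(n), rate=rate), jump_idx
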