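"""The 18-channel 10-20 montage used throughout the package.

Channel laterality follows the 10-20 naming convention: odd site numbers
are left-hemisphere electrodes, even numbers right, and a trailing "z"
marks the midline.
"""

from __future__ import annotations

#: Electrode order of the 18-channel cap (ground Cz excluded).
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F7", "Fz", "F4", "F8",
    "T3", "T4", "C3", "C4", "T5",
    "P3", "Pz", "P4", "T6", "O1", "O2",
)

EEG_RATE_HZ = 500.0
GAZE_RATE_HZ = 60.0


def hemisphere(channel: str) -> str:
    """Return ``left``, ``right`` or ``midline`` for a 10-20 channel name."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown 10-20 channel name: {channel!r}")
    tail = channel[-1].lower()
    if tail == "z":
        return "midline"
    return "left" if int(tail) % 2 == 1 else "right"
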