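"""Visual pattern encoding and competitive filtering.

A visual pattern is a 5-channel saliency vector ordered ``[R, G, B,
upright, inverted]``.  A colour-and-shape stimulus activates one colour
channel (or all three for white) at saliency ``10 * CI`` and one shape
channel at saliency 10, where CI is the colour-intensity scalar.  When two
patterns are presented simultaneously, the non-attended pattern inhibits
the attended one channel-by-channel, so cues shared by both patterns cancel
and only the distinguishing cues drive the network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VisualPattern",
    "CHANNELS",
    "encode",
    "competitive_filter",
    "normalize_cues",
    "pattern_library",
    "write_pattern_csv",
    "InputError",
]

CHANNELS = ("R", "G", "B", "upright", "inverted")
BASE_SALIENCY = 10.0

_COLOR_CHANNELS = {
    "green": (1,),
    "blue": (2,),
    "white": (0, 1, 2),
    "none": (),
}
_SHAPE_CHANNELS = {"upright": 3, "inverted": 4, "none": None}


class InputError(ValueError):
    """Raised for malformed stimulus specifications."""


@dataclass(frozen=True)
class VisualPattern:
    """A named 5-channel stimulus with its colour-intensity scalar."""

    name: str
    channels: tuple[float, ...]
    ci: float = 1.0

    def __post_init__(self) -> None:
        if len(self.channels) != 5:
            raise InputError("a visual pattern has exactly 5 channels")
        if any(c < 0 for c in self.channels):
            raise InputError("channel saliencies must be non-negative")
        if self.channels[3] > 0 and self.channels[4] > 0:
            raise InputError("at most one shape channel may be active")
        if self.ci < 0:
            raise InputError("colour intensity must be non-negative")

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.channels, dtype=float)


def encode(color: str, shape: str, ci: float = 1.0) -> VisualPattern:
    """Encode a colour/shape stimulus as a 5-channel pattern.

    The selected colour channel(s) carry ``10 * ci`` (white activates R, G
    and B equally) and the shape channel carries 10.  ``ci`` may exceed 1,
    in which case the colour cue is more salient than the shape cue.
    """
    if color not in _COLOR_CHANNELS:
        raise InputError(f"unknown color {color!r}; expected one of "
                         f"{sorted(_COLOR_CHANNELS)}")
    if shape not in _SHAPE_CHANNELS:
        raise InputError(f"unknown shape {shape!r}; expected one of "
                         f"{sorted(_SHAPE_CHANNELS)}")
    if ci < 0:
        raise InputError("ci must be non-negative")
    channels = [0.0] * 5
    for idx in _COLOR_CHANNELS[color]:
        channels[idx] = BASE_SALIENCY * ci
    shape_idx = _SHAPE_CHANNELS[shape]
    if shape_idx is not None:
        channels[shape_idx] = BASE_SALIENCY
    name_bits = [s for s in (shape, color) if s != "none"]
    name = "-".join(name_bits + ["T"]) if name_bits else "blank"
    return VisualPattern(name=name, channels=tuple(channels), ci=ci)


def competitive_filter(current: VisualPattern, other: VisualPattern) -> np.ndarray:
    """One-to-one subtractive inhibition of ``current`` by ``other``.

    Returns the rectified elementwise difference ``max(current - other, 0)``.
    Channels identical in both patterns (shared cues, i.e. noise for the
    decision) cancel exactly and do not reach the network.
    """
    return np.maximum(current.vector - other.vector, 0.0)


def normalize_cues(raw) -> np.ndarray:
    """Map non-negative cue values onto the network input range [1, 20].

    Each value is mapped by ``p = 1 + 19 * x / x_max``; order is preserved
    and the largest cue always maps to 20 (all-equal inputs map to all-20).
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2:
        raise InputError("need at least two cues")
    if np.any(x < 0):
        raise InputError("cue values must be non-negative")
    x_max = x.max()
    if x_max == 0:
        raise InputError("at least one cue must be positive")
    return 1.0 + 19.0 * x / x_max


def pattern_library(ci: float = 1.0) -> dict[str, VisualPattern]:
    """The named stimuli used throughout the conditioning experiments."""
    lib: dict[str, VisualPattern] = {}
    for shape in ("upright", "inverted"):
        for color in ("green", "blue", "white"):
            p = encode(color, shape, ci)
            lib[p.name] = p
    return lib


def write_pattern_csv(path, patterns: dict[str, VisualPattern]) -> None:
    """Fixture writer: one row per pattern, name followed by 5 channels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", *CHANNELS])
        for name in sorted(patterns):
            w.writerow([name, *patterns[name].vector.tolist()])
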