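"""Gesture vocabulary of the cursor interface.

Nine hand states drive the cursor: rest (``G0``), four basic wrist
movements mapped to screen directions, and four compound gestures that
combine two basic movements into a diagonal.

==========  =======================  ==========
id          movement                 direction
==========  =======================  ==========
G0          hand at rest             none
G1          wrist flexion            left
G2          wrist extension          right
G3          radial deviation         up
G4          ulnar deviation          down
G5          extension + radial       right-up
G6          flexion + radial         left-up
G7          extension + ulnar        right-down
G8          flexion + ulnar          left-down
==========  =======================  ==========
"""

from __future__ import annotations

import math

REST = "G0"

BASIC = ("G1", "G2", "G3", "G4")
COMPOUND = ("G5", "G6", "G7", "G8")
DIRECTIONAL = BASIC + COMPOUND
ALL = (REST,) + DIRECTIONAL

#: parents of each compound gesture
COMPOUND_PARENTS = {
    "G5": ("G2", "G3"),
    "G6": ("G1", "G3"),
    "G7": ("G2", "G4"),
    "G8": ("G1", "G4"),
}

#: the gesture producing the opposite screen movement
OPPOSITE = {
    "G0": "G0",
    "G1": "G2",
    "G2": "G1",
    "G3": "G4",
    "G4": "G3",
    "G5": "G8",
    "G8": "G5",
    "G6": "G7",
    "G7": "G6",
}

#: unit screen direction (x rightward, y upward) of each directional gesture
_S = 1.0 / math.sqrt(2.0)
DIRECTION = {
    "G1": (-1.0, 0.0),
    "G2": (1.0, 0.0),
    "G3": (0.0, 1.0),
    "G4": (0.0, -1.0),
    "G5": (_S, _S),
    "G6": (-_S, _S),
    "G7": (_S, -_S),
    "G8": (-_S, -_S),
}


def nearest_gesture(angle: float) -> str:
    """Directional gesture whose screen direction is closest to ``angle``.

    ``angle`` is measured counter-clockwise from the +x axis, in radians.
    The eight gestures tile the circle in 45-degree sectors.
    """
    sector = round(angle / (math.pi / 4.0)) % 8
    return (
        "G2",  # 0
        "G5",  # 45
        "G3",  # 90
        "G6",  # 135
        "G1",  # 180
        "G8",  # 225
        "G4",  # 270
        "G7",  # 315
    )[sector]
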