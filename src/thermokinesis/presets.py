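"""Per-temperature kinematic presets.

Anchor values at the five assay temperatures (18, 22, 26, 30, 33 degC).
Mean interbout interval and mean displacement follow the printed
endpoints with a plateau above 26 degC; the turn and flip probabilities
interpolate linearly in temperature between their printed endpoints.
The turn-amplitude mean and forward-angle width are not anchored to any
printed value and are exposed here so they can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

ANCHOR_TEMPS = np.array([18.0, 22.0, 26.0, 30.0, 33.0])

ANCHOR_MEAN_IBI = np.array([1.4, 1.15, 1.0, 1.0, 1.0])  # s
ANCHOR_MEAN_DISP = np.array([1.0, 1.25, 1.5, 1.5, 1.5])  # mm

#: linear in T between the endpoints 0.3 (18 degC) and 0.8 (33 degC)
ANCHOR_P_TURN = 0.3 + 0.5 * (ANCHOR_TEMPS - 18.0) / 15.0
#: linear in T between the endpoints 0.22 (18 degC) and 0.45 (33 degC)
ANCHOR_P_FLIP = 0.22 + 0.23 * (ANCHOR_TEMPS - 18.0) / 15.0

DEFAULT_MEAN_TURN_ANGLE = 0.6  # rad, not anchored to a printed value
DEFAULT_FWD_ANGLE_SD = 0.05  # rad


@dataclass(frozen=True)
class KinematicPreset:
    """Scalar bout-level parameters of one temperature condition."""

    temperature: float  # degC
    mean_ibi: float  # s
    mean_disp: float  # mm, post-correction (turn bouts travel 1.6x more)
    p_turn: float
    p_flip: float
    mean_turn_angle: float = DEFAULT_MEAN_TURN_ANGLE  # rad, E|dtheta| of turns
    fwd_angle_sd: float = DEFAULT_FWD_ANGLE_SD  # rad

    def with_overrides(self, **kwargs) -> "KinematicPreset":
        return replace(self, **kwargs)


def preset_for(temperature: float) -> KinematicPreset:
    """Preset at an arbitrary temperature, linearly interpolated between
    the five anchors (clamped outside [18, 33])."""
    t = float(temperature)
    return KinematicPreset(
        temperature=t,
        mean_ibi=float(np.interp(t, ANCHOR_TEMPS, ANCHOR_MEAN_IBI)),
        mean_disp=float(np.interp(t, ANCHOR_TEMPS, ANCHOR_MEAN_DISP)),
        p_turn=float(np.interp(t, ANCHOR_TEMPS, ANCHOR_P_TURN)),
        p_flip=float(np.interp(t, ANCHOR_TEMPS, ANCHOR_P_FLIP)),
    )


def preset_by_name(name: str) -> KinematicPreset:
    """Look up a preset by label such as ``"18C"`` or ``"26C"``."""
    label = name.upper().rstrip("C")
    try:
        temperature = float(label)
    except ValueError as exc:
        raise KeyError(f"unknown preset {name!r}") from exc
    if not (ANCHOR_TEMPS[0] <= temperature <= ANCHOR_TEMPS[-1]):
        raise KeyError(f"preset temperature {temperature} outside 18-33 degC")
    return preset_for(temperature)


ALL_PRESETS = {f"{int(t)}C": preset_for(t) for t in ANCHOR_TEMPS}
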