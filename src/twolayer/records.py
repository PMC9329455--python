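"""Domain record types shared across the package.

Two kinds of classified objects are supported:

* :class:`TrajectoryTrial` — one 13-second joystick trial from the virtual
  T-maze paradigm, sampled as 3000 x-deflections and 3000 y-deflections
  in [-1, 1] (x negative = left, y positive = forward).
* :class:`ICComponent` — one EEG independent component summarized by its
  1500-sample mean time-course, a 32-electrode topography and a 70-band
  (1–70 Hz) power spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Samples per trajectory axis (3000 samples covering a 13 s trial).
TRAJECTORY_SAMPLES = 3000
#: Default trial duration in seconds.
TRIAL_DURATION_S = 13.0

#: Feature-block lengths of an independent component record.
IC_TIMECOURSE_SAMPLES = 1500
IC_TOPOGRAPHY_CHANNELS = 32
IC_SPECTRUM_BANDS = 70

#: Behavior label values (1-based, matching the category numbering used
#: throughout: 1 fleeing, 2/3 approach-safety left/right, 4/5 reach-out
#: left/right, 6 behavioral conflict).
FLEEING = 1
APPROACH_SAFETY_LEFT = 2
APPROACH_SAFETY_RIGHT = 3
REACH_OUT_LEFT = 4
REACH_OUT_RIGHT = 5
CONFLICT = 6
#: Sentinel for trials matched by no rule.
UNCLASSIFIED = 0

BEHAVIOR_LABELS = (FLEEING, APPROACH_SAFETY_LEFT, APPROACH_SAFETY_RIGHT,
                   REACH_OUT_LEFT, REACH_OUT_RIGHT, CONFLICT)

ARTIFACT = "artifact"
SIGNAL = "signal"


def _as_series(values, name: str, length: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != length:
        raise ValueError(f"{name} must be a 1-D series of length {length}, "
                         f"got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite samples")
    return arr


@dataclass
class TrajectoryTrial:
    """One joystick trial: paired x/y deflection series plus identifiers."""

    participant_id: int
    trial_index: int
    condition: int
    x: np.ndarray
    y: np.ndarray
    duration_s: float = TRIAL_DURATION_S

    def __post_init__(self) -> None:
        self.x = _as_series(self.x, "x", TRAJECTORY_SAMPLES)
        self.y = _as_series(self.y, "y", TRAJECTORY_SAMPLES)
        for name, arr in (("x", self.x), ("y", self.y)):
            if np.any(np.abs(arr) > 1.0 + 1e-12):
                raise ValueError(f"{name} samples must lie in [-1, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def dt(self) -> float:
        """Seconds per sample."""
        return self.duration_s / TRAJECTORY_SAMPLES


@dataclass
class ICComponent:
    """One independent component: time-course, topography, spectrum, id."""

    mean_timecourse: np.ndarray
    topography: np.ndarray
    spectrum: np.ndarray
    participant_id: int
    label: str | None = None

    def __post_init__(self) -> None:
        self.mean_timecourse = _as_series(
            self.mean_timecourse, "mean_timecourse", IC_TIMECOURSE_SAMPLES)
        self.topography = _as_series(
            self.topography, "topography", IC_TOPOGRAPHY_CHANNELS)
        self.spectrum = _as_series(self.spectrum, "spectrum", IC_SPECTRUM_BANDS)
        if np.any(self.spectrum < 0):
            raise ValueError("spectrum entries must be non-negative")
        if self.label is not None and self.label not in (ARTIFACT, SIGNAL):
            raise ValueError(f"label must be {ARTIFACT!r} or {SIGNAL!r}")
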