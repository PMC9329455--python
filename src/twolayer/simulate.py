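"""Synthetic data with the structure of both classification problems.

Two generators are provided:

* T-maze joystick trials — parameterized deflection templates, one per
  behavior category, with onset jitter and additive Gaussian measurement
  noise.  Templates are smooth splines built so that the rule system in
  :mod:`twolayer.rules` recovers the intended label at zero noise.
* EEG independent components — kind-specific recipes for the canonical
  artifact families (blink, lateral eye movement, muscle, cardiac pulse,
  line noise) and two signal families (posterior alpha, broadband 1/f),
  each producing a time-course, a 32-slot topography and a 70-band
  spectrum.

All randomness flows through one seeded generator per dataset; there is
no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .records import (ARTIFACT, BEHAVIOR_LABELS, CONFLICT, SIGNAL,
                      IC_SPECTRUM_BANDS, IC_TIMECOURSE_SAMPLES,
                      IC_TOPOGRAPHY_CHANNELS, TRAJECTORY_SAMPLES,
                      TRIAL_DURATION_S, ICComponent, TrajectoryTrial)

# -- T-maze trajectories ---------------------------------------------------

CONFLICT_VARIANTS = ("late-onset", "mid-switch", "sloppy")

#: Default per-condition category mixes (rows: conditions 1-5 = negative,
#: positive, approach-avoidance, approach-approach, ambiguous; columns:
#: behavior categories 1-6).  Negative trials are dominated by fleeing and
#: approach-safety, positive and approach-approach trials by reaching out,
#: and the conflict conditions carry a larger share of category 6.
DEFAULT_CATEGORY_MIX = {
    1: (0.35, 0.25, 0.25, 0.02, 0.03, 0.10),
    2: (0.02, 0.03, 0.05, 0.40, 0.40, 0.10),
    3: (0.20, 0.15, 0.15, 0.15, 0.15, 0.20),
    4: (0.02, 0.03, 0.05, 0.40, 0.35, 0.15),
    5: (0.15, 0.15, 0.15, 0.20, 0.15, 0.20),
}


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Study-scale, noise level and category structure of simulated trials."""

    n_participants: int = 54
    trials_per_condition: int = 20
    conditions: int = 5
    category_mix: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    onset_mean_s: float = 0.5
    onset_sd_s: float = 0.15
    noise_sd: float = 0.02
    conflict_variants: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("participant and trial counts must be positive")
        if self.conditions < 1:
            raise ValueError("conditions must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for cond, mix in self.category_mix.items():
            if len(mix) != 6 or abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"category_mix for condition {cond} must be a "
                                 "probability vector over 6 labels")
        if abs(sum(self.conflict_variants) - 1.0) > 1e-9:
            raise ValueError("conflict_variants weights must sum to 1")


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    u = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _bounded_smooth_noise(rng: np.random.Generator, n: int,
                          smooth_sigma: float = 25.0) -> np.ndarray:
    """Low-pass Gaussian noise rescaled to max |value| = 1."""
    raw = gaussian_filter1d(rng.normal(size=n), smooth_sigma)
    peak = np.max(np.abs(raw))
    return raw / peak if peak > 0 else raw


def simulate_trajectory(label: int, condition: int,
                        config: TrajectorySimConfig,
                        rng: np.random.Generator,
                        participant_id: int = 1,
                        trial_index: int = 1) -> TrajectoryTrial:
    """One trial whose intended behavior category is ``label``.

    Conflict trials (label 6) draw one of three mechanistic variants:
    late onset (> 1.5 s), a mid-trial backward-to-forward reversal
    without turning, or a high-jitter "sloppy" execution of such a
    reversal.
    """
    if label not in BEHAVIOR_LABELS:
        raise ValueError(f"label must be in 1..6, got {label!r}")
    n = TRAJECTORY_SAMPLES
    t = np.arange(n) * (TRIAL_DURATION_S / n)
    onset = float(np.clip(rng.normal(config.onset_mean_s, config.onset_sd_s),
                          0.15, 1.2))
    x = np.zeros(n)
    y = np.zeros(n)

    if label == 1:  # fleeing: deep backward ramp, no turning
        y = -0.9 * _smoothstep(t, onset, onset + 0.5)
    elif label in (2, 3):  # approach safety: backward phase, turn, forward
        sgn = -1.0 if label == 2 else 1.0
        y = (-0.8 * _smoothstep(t, onset, onset + 0.4)
             + 1.6 * _smoothstep(t, onset + 1.2, onset + 2.0))
        x = sgn * 0.6 * _smoothstep(t, onset + 1.0, onset + 1.6)
    elif label in (4, 5):  # reach out: forward ramp, later lateral drift
        sgn = -1.0 if label == 4 else 1.0
        y = 0.9 * _smoothstep(t, onset, onset + 0.6)
        x = sgn * 0.4 * _smoothstep(t, 4.0, 4.8)
    else:  # behavioral conflict
        variant = CONFLICT_VARIANTS[
            rng.choice(3, p=np.asarray(config.conflict_variants))]
        if variant == "late-onset":
            late = float(rng.uniform(1.8, 3.0))
            y = 0.9 * _smoothstep(t, late, late + 0.6)
        elif variant == "mid-switch":
            switch = onset + 2.6
            y = (-0.65 * _smoothstep(t, onset, onset + 0.4)
                 + 1.45 * _smoothstep(t, switch, switch + 0.8))
        else:  # sloppy: jittery execution of a reversal, no turning
            y = (-0.5 * _smoothstep(t, onset, onset + 0.4)
                 + 1.0 * _smoothstep(t, onset + 2.6, onset + 3.4))
            envelope = _smoothstep(t, onset, onset + 0.5)
            y = y + 0.25 * _bounded_smooth_noise(rng, n) * envelope

    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, n)
        y = y + rng.normal(0.0, config.noise_sd, n)
    return TrajectoryTrial(participant_id=participant_id,
                           trial_index=trial_index, condition=condition,
                           x=np.clip(x, -1.0, 1.0), y=np.clip(y, -1.0, 1.0))


def simulate_tmaze_dataset(config: TrajectorySimConfig,
                           ) -> tuple[list[TrajectoryTrial], list[int]]:
    """Full simulated study: participants x conditions x trials.

    Labels are drawn per condition from ``category_mix``; the returned
    label list holds the generator's intended category for each trial.
    """
    rng = np.random.default_rng(config.seed)
    trials: list[TrajectoryTrial] = []
    labels: list[int] = []
    for pid in range(1, config.n_participants + 1):
        for cond in range(1, config.conditions + 1):
            mix = np.asarray(config.category_mix.get(
                cond, DEFAULT_CATEGORY_MIX[1 + (cond - 1) % 5]))
            for idx in range(1, config.trials_per_condition + 1):
                label = int(rng.choice(6, p=mix)) + 1
                trials.append(simulate_trajectory(
                    label, cond, config, rng,
                    participant_id=pid, trial_index=idx))
                labels.append(label)
    return trials, labels


# -- EEG independent components -------------------------------------------

ARTIFACT_KINDS = ("blink", "lateral-eye", "muscle", "pulse", "line-noise")
SIGNAL_KINDS = ("alpha-posterior", "broadband-1/f")

#: Electrode-slot semantics of the fixed 32-slot montage (0-based).
FRONTAL_SLOTS = (0, 1, 2, 3, 4, 5)
TEMPORAL_SLOTS = (12, 13, 18, 19)
POSTERIOR_SLOTS = (26, 27, 28, 29, 30, 31)
EDGE_SLOTS = (0, 1, 6, 7, 12, 13, 18, 19, 24, 25, 30, 31)

#: Nominal sampling rate of the simulated time-courses (Hz); 1500 samples
#: then cover 6 s of component activation.
IC_SAMPLING_HZ = 250.0


@dataclass(frozen=True)
class ICSimConfig:
    """Study-scale and class structure of simulated IC datasets."""

    n_participants: int = 51
    components_per_participant: int = 32
    artifact_fraction: float = 0.4
    artifact_kinds: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    signal_kinds: tuple[float, ...] = (0.5, 0.5)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.components_per_participant < 1:
            raise ValueError("participant and component counts must be positive")
        if not 0 <= self.artifact_fraction <= 1:
            raise ValueError("artifact_fraction must lie in [0, 1]")
        for name, weights, size in (("artifact_kinds", self.artifact_kinds, 5),
                                    ("signal_kinds", self.signal_kinds, 2)):
            if len(weights) != size or abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be {size} weights summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _kind_recipe(kind: str, rng: np.random.Generator,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = IC_TIMECOURSE_SAMPLES
    t = np.arange(n) / IC_SAMPLING_HZ
    bands = np.arange(1, IC_SPECTRUM_BANDS + 1, dtype=float)
    topo = np.zeros(IC_TOPOGRAPHY_CHANNELS)
    if kind == "blink":
        tc = np.zeros(n)
        for center in rng.uniform(0.3, t[-1] - 0.3, size=rng.integers(3, 7)):
            width = rng.uniform(0.15, 0.25)  # 300-500 ms lobes
            tc += np.exp(-0.5 * ((t - center) / width) ** 2)
        topo[[0, 1]] = (1.0, 0.9)
        topo[[2, 3]] = 0.4
        spectrum = np.exp(-(bands - 1) / 1.2)
    elif kind == "lateral-eye":
        tc = np.sign(gaussian_filter1d(rng.normal(size=n), 60.0))
        tc = gaussian_filter1d(tc, 5.0)  # step-like with soft edges
        topo[[0, 2, 4]] = 1.0
        topo[[1, 3, 5]] = -1.0
        spectrum = np.exp(-(bands - 1) / 2.0)
    elif kind == "muscle":
        tc = rng.normal(size=n)
        topo[list(EDGE_SLOTS)] = rng.uniform(0.5, 1.0, size=len(EDGE_SLOTS))
        spectrum = 0.1 + 1.0 / (1.0 + np.exp(-(bands - 20.0) / 2.0))
    elif kind == "pulse":
        period = rng.uniform(0.9, 1.1)  # ~1 Hz cardiac rhythm
        phase = rng.uniform(0.0, period)
        tc = np.zeros(n)
        beat = phase
        while beat < t[-1]:
            tc += np.exp(-0.5 * ((t - beat) / 0.05) ** 2)
            beat += period
        topo[list(TEMPORAL_SLOTS)] = 1.0
        spectrum = (np.exp(-(bands - 1) / 1.0)
                    + 0.3 * np.exp(-0.5 * (bands - 2.0) ** 2)
                    + 0.1 * np.exp(-0.5 * (bands - 3.0) ** 2))
    elif kind == "line-noise":
        tc = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        topo[:] = rng.uniform(0.1, 0.3, size=topo.size)
        spectrum = 0.02 / bands
        spectrum[49] += 10.0  # 50 Hz mains line
    elif kind == "alpha-posterior":
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
        tc = envelope * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        topo[list(POSTERIOR_SLOTS)] = 1.0
        spectrum = 1.0 / bands + 2.0 * np.exp(-0.5 * ((bands - 10.0) / 1.5) ** 2)
    elif kind == "broadband-1/f":
        tc = gaussian_filter1d(np.cumsum(rng.normal(size=n)), 3.0)
        tc = (tc - tc.mean()) / (tc.std() + 1e-12)
        # widely distributed loading with mild smooth variation
        topo = 0.3 + 0.1 * gaussian_filter1d(rng.normal(size=topo.size), 2.0)
        spectrum = 1.5 / bands
    else:
        raise ValueError(f"unknown component kind {kind!r}")
    return tc, topo, spectrum


def simulate_ic_component(kind: str, config: ICSimConfig,
                          rng: np.random.Generator,
                          participant_id: int = 1) -> ICComponent:
    """One independent component of the requested kind, with its label."""
    tc, topo, spectrum = _kind_recipe(kind, rng)
    if config.noise_sd > 0:
        tc = tc + rng.normal(0.0, config.noise_sd, tc.size)
        topo = topo + rng.normal(0.0, config.noise_sd, topo.size)
        spectrum = spectrum + rng.normal(0.0, config.noise_sd, spectrum.size)
    label = ARTIFACT if kind in ARTIFACT_KINDS else SIGNAL
    return ICComponent(mean_timecourse=tc, topography=topo,
                       spectrum=np.clip(spectrum, 0.0, None),
                       participant_id=participant_id, label=label)


def simulate_ic_dataset(config: ICSimConfig,
                        ) -> tuple[list[ICComponent], list[str]]:
    """Participants x components collection with kind labels attached."""
    rng = np.random.default_rng(config.seed)
    components: list[ICComponent] = []
    kinds: list[str] = []
    for pid in range(1, config.n_participants + 1):
        for _ in range(config.components_per_participant):
            if rng.random() < config.artifact_fraction:
                kind = ARTIFACT_KINDS[
                    rng.choice(len(ARTIFACT_KINDS),
                               p=np.asarray(config.artifact_kinds))]
            else:
                kind = SIGNAL_KINDS[
                    rng.choice(len(SIGNAL_KINDS),
                               p=np.asarray(config.signal_kinds))]
            components.append(simulate_ic_component(kind, config, rng, pid))
            kinds.append(kind)
    return components, kinds
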