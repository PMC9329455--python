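"""Expert rule system for the six T-maze behavior categories.

The rules operationalize the manual criteria an expert rater applies to
joystick trajectories (deflection in [-1, 1]; x negative = left, y
positive = forward):

1. *Fleeing* — sustained backward deflection above 75% of full scale
   with sideways deflection staying under 50% in the first 8 s.
2./3. *Approach safety (left/right)* — sideways deflection above 15%
   together with a backward-to-forward sign change of y in the first 8 s.
4./5. *Reach out (left/right)* — forward deflection above 50% of full
   scale in the first 8 s with backward deflection under 10% in the
   first 4 s.
6. *Behavioral conflict* — reaction onset later than 1.5 s, a mid-trial
   change of behavior, or markedly degraded execution relative to the
   participant's other trials.

Thresholds are fractions of the device maximum (full joystick
deflection = 1.0).  Categories are made mutually exclusive by a fixed
precedence: latency-conflict, reach-out, fleeing, approach-safety,
switch/outlier-conflict, unclassified.  Sustained thresholds use a dwell
fraction of the window rather than single-sample crossings so the rules
are robust to measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import (APPROACH_SAFETY_LEFT, APPROACH_SAFETY_RIGHT, CONFLICT,
                      FLEEING, REACH_OUT_LEFT, REACH_OUT_RIGHT, UNCLASSIFIED,
                      TrajectoryTrial)


@dataclass(frozen=True)
class RuleParams:
    """Thresholds and windows of the behavioral rule system.

    All *_frac parameters are fractions of full joystick deflection in
    (0, 1]; windows are in seconds and must not exceed the trial
    duration.
    """

    flee_backward_frac: float = 0.75
    flee_sideways_max_frac: float = 0.50
    safety_sideways_min_frac: float = 0.15
    reach_forward_min_frac: float = 0.50
    reach_backward_max_frac: float = 0.10
    early_window_s: float = 8.0
    reach_backward_window_s: float = 4.0
    conflict_latency_s: float = 1.5
    movement_onset_frac: float = 0.10
    dwell_frac: float = 0.20
    outlier_z: float = 3.0
    #: minimum duration of each phase of a backward->forward sign change
    phase_min_s: float = 0.25
    #: minimum duration of a movement-dominant segment for the
    #: change-of-behavior conflict clause
    switch_segment_min_s: float = 1.0

    def __post_init__(self) -> None:
        fracs = (self.flee_backward_frac, self.flee_sideways_max_frac,
                 self.safety_sideways_min_frac, self.reach_forward_min_frac,
                 self.reach_backward_max_frac, self.movement_onset_frac,
                 self.dwell_frac)
        if any(not 0 < f <= 1 for f in fracs):
            raise ValueError("fraction parameters must lie in (0, 1]")
        if self.early_window_s <= 0 or self.reach_backward_window_s <= 0:
            raise ValueError("windows must be positive")
        if self.conflict_latency_s <= 0 or self.outlier_z <= 0:
            raise ValueError("conflict_latency_s and outlier_z must be positive")


def onset_latency(trial: TrajectoryTrial, params: RuleParams = RuleParams()) -> float:
    """Time of the first sample where max(|x|, |y|) exceeds the onset
    threshold, in seconds; ``inf`` if movement never starts."""
    moving = np.maximum(np.abs(trial.x), np.abs(trial.y)) > params.movement_onset_frac
    idx = np.flatnonzero(moving)
    if idx.size == 0:
        return math.inf
    return float(idx[0]) * trial.dt


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _turn_direction(x_early: np.ndarray) -> int:
    """Left/right of the turning movement: sign of x at maximal |x|.

    Returns a *left* label offset (0) for negative deflection, *right*
    (1) otherwise.
    """
    idx = int(np.argmax(np.abs(x_early)))
    return 0 if x_early[idx] < 0 else 1


def _has_sign_change(y_early: np.ndarray, params: RuleParams, dt: float) -> bool:
    """Backward-then-forward movement with both phases sustained."""
    phase = max(1, math.ceil(params.phase_min_s / dt))
    neg_runs = [r for r in _true_runs(y_early < -params.movement_onset_frac)
                if r[1] - r[0] >= phase]
    pos_runs = [r for r in _true_runs(y_early > params.movement_onset_frac)
                if r[1] - r[0] >= phase]
    if not neg_runs or not pos_runs:
        return False
    first_neg_end = min(stop for _, stop in neg_runs)
    last_pos_start = max(start for start, _ in pos_runs)
    return first_neg_end <= last_pos_start


def _has_behavior_switch(trial: TrajectoryTrial, params: RuleParams) -> bool:
    """Both a backward- and a forward-dominant segment of sustained length."""
    seg = max(1, math.ceil(params.switch_segment_min_s / trial.dt))
    backward = any(stop - start >= seg for start, stop in
                   _true_runs(trial.y < -params.movement_onset_frac))
    forward = any(stop - start >= seg for start, stop in
                  _true_runs(trial.y > params.movement_onset_frac))
    return backward and forward


def _roughness(trial: TrajectoryTrial) -> float:
    """Mean absolute per-sample change of x plus y (execution jitter)."""
    return float(np.mean(np.abs(np.diff(trial.x))) +
                 np.mean(np.abs(np.diff(trial.y))))


def performance_outlier(trial: TrajectoryTrial,
                        participant_trials: Sequence[TrajectoryTrial],
                        params: RuleParams = RuleParams()) -> bool:
    """Markedly degraded execution relative to the participant's trials.

    The trial's roughness score must exceed the participant's median
    roughness by more than ``outlier_z`` robust standard deviations
    (1.4826 * MAD).  With zero dispersion (MAD = 0) a trial is an
    outlier only if its score strictly exceeds the median.
    """
    if len(participant_trials) < 5:
        raise ValueError("need at least 5 reference trials from the participant")
    scores = np.array([_roughness(t) for t in participant_trials])
    median = float(np.median(scores))
    mad = float(np.median(np.abs(scores - median)))
    return _roughness(trial) > median + params.outlier_z * 1.4826 * mad


def classify_trial(trial: TrajectoryTrial,
                   params: RuleParams = RuleParams(),
                   participant_trials: Sequence[TrajectoryTrial] | None = None,
                   ) -> int:
    """Assign one of the six behavior categories (or ``UNCLASSIFIED``).

    Rules are evaluated in precedence order: (a) conflict by late onset,
    (b) reach-out, (c) fleeing, (d) approach-safety, (e) conflict by
    behavior change or degraded execution, (f) unclassified.
    ``participant_trials``, when given, enables the degraded-execution
    clause of (e).
    """
    dt = trial.dt
    n = trial.x.size
    early = min(n, int(np.floor(n * params.early_window_s / trial.duration_s)))
    back_window = min(n, int(np.floor(n * params.reach_backward_window_s
                                      / trial.duration_s)))
    dwell = params.dwell_frac * early
    x_early = trial.x[:early]
    y_early = trial.y[:early]

    # (a) conflict by reaction latency
    if onset_latency(trial, params) > params.conflict_latency_s:
        return CONFLICT

    # (b) reach-out: sustained forward deflection, no early backward phase
    forward_dwell = int(np.sum(y_early > params.reach_forward_min_frac))
    early_backward = float(np.max(-np.minimum(trial.y[:back_window], 0.0)))
    if forward_dwell >= dwell and early_backward < params.reach_backward_max_frac:
        return REACH_OUT_LEFT + _turn_direction(x_early)

    # (c) fleeing: sustained deep backward deflection, no turning
    backward_dwell = int(np.sum(-y_early > params.flee_backward_frac))
    if (backward_dwell >= dwell
            and bool(np.all(np.abs(x_early) < params.flee_sideways_max_frac))):
        return FLEEING

    # (d) approach-safety: turning plus backward->forward sign change
    if (bool(np.any(np.abs(x_early) > params.safety_sideways_min_frac))
            and _has_sign_change(y_early, params, dt)):
        return APPROACH_SAFETY_LEFT + _turn_direction(x_early)

    # (e) conflict: change of behavior, or degraded execution
    if _has_behavior_switch(trial, params):
        return CONFLICT
    if participant_trials is not None and len(participant_trials) >= 5:
        if performance_outlier(trial, participant_trials, params):
            return CONFLICT

    return UNCLASSIFIED


def classify_trials(trials: Iterable[TrajectoryTrial],
                    params: RuleParams = RuleParams(),
                    use_outlier_rule: bool = False) -> list[int]:
    """Label a collection of trials.

    With ``use_outlier_rule`` the degraded-execution conflict clause is
    enabled, using each participant's own trials as the reference set.
    """
    trials = list(trials)
    by_participant: dict[int, list[TrajectoryTrial]] = {}
    if use_outlier_rule:
        for t in trials:
            by_participant.setdefault(t.participant_id, []).append(t)
    labels = []
    for t in trials:
        ref = by_participant.get(t.participant_id) if use_outlier_rule else None
        if ref is not None and len(ref) < 5:
            ref = None
        labels.append(classify_trial(t, params, ref))
    return labels
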