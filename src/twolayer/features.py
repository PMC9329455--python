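"""Input-vector layouts and one-hot targets for both classifiers.

The joystick layout concatenates, in order, the 3000 x-samples, the 3000
y-samples, the participant id, the trial index within its condition, and
the condition number (6003 elements).  The component layout concatenates
the 1500-sample mean time-course, the 32-slot topography, the 70-band
spectrum and the participant id (1603 elements).  Identifier elements
enter as raw numeric values here; feature standardization happens inside
the classifier on the training split.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sp_signal

from .records import (IC_SPECTRUM_BANDS, IC_TIMECOURSE_SAMPLES,
                      IC_TOPOGRAPHY_CHANNELS, TRAJECTORY_SAMPLES,
                      ICComponent, TrajectoryTrial)

#: Half-open 0-based slices of the joystick feature vector.
TMAZE_VECTOR_LENGTH = 2 * TRAJECTORY_SAMPLES + 3
TMAZE_BLOCKS = {
    "x": slice(0, TRAJECTORY_SAMPLES),
    "y": slice(TRAJECTORY_SAMPLES, 2 * TRAJECTORY_SAMPLES),
    "participant_id": slice(2 * TRAJECTORY_SAMPLES, 2 * TRAJECTORY_SAMPLES + 1),
    "trial_index": slice(2 * TRAJECTORY_SAMPLES + 1, 2 * TRAJECTORY_SAMPLES + 2),
    "condition": slice(2 * TRAJECTORY_SAMPLES + 2, 2 * TRAJECTORY_SAMPLES + 3),
}

#: Half-open 0-based slices of the component feature vector.
IC_VECTOR_LENGTH = (IC_TIMECOURSE_SAMPLES + IC_TOPOGRAPHY_CHANNELS
                    + IC_SPECTRUM_BANDS + 1)
IC_BLOCKS = {
    "mean_timecourse": slice(0, IC_TIMECOURSE_SAMPLES),
    "topography": slice(IC_TIMECOURSE_SAMPLES,
                        IC_TIMECOURSE_SAMPLES + IC_TOPOGRAPHY_CHANNELS),
    "spectrum": slice(IC_TIMECOURSE_SAMPLES + IC_TOPOGRAPHY_CHANNELS,
                      IC_TIMECOURSE_SAMPLES + IC_TOPOGRAPHY_CHANNELS
                      + IC_SPECTRUM_BANDS),
    "participant_id": slice(IC_VECTOR_LENGTH - 1, IC_VECTOR_LENGTH),
}


def build_tmaze_vector(trial: TrajectoryTrial) -> np.ndarray:
    """6003-element vector: [x(3000), y(3000), pid, trial, condition]."""
    return np.concatenate([
        trial.x, trial.y,
        [float(trial.participant_id), float(trial.trial_index),
         float(trial.condition)],
    ])


def build_ic_vector(component: ICComponent) -> np.ndarray:
    """1603-element vector: [time-course(1500), topo(32), spectrum(70), pid]."""
    return np.concatenate([
        component.mean_timecourse, component.topography, component.spectrum,
        [float(component.participant_id)],
    ])


def build_tmaze_matrix(trials: Iterable[TrajectoryTrial]) -> np.ndarray:
    """Stack trial vectors into an (n_trials, 6003) matrix."""
    return np.vstack([build_tmaze_vector(t) for t in trials])


def build_ic_matrix(components: Iterable[ICComponent]) -> np.ndarray:
    """Stack component vectors into an (n_components, 1603) matrix."""
    return np.vstack([build_ic_vector(c) for c in components])


def build_targets(labels: Sequence[int], n_classes: int) -> np.ndarray:
    """One-hot target rows from 1-based class labels."""
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D sequence")
    if np.any(labels < 1) or np.any(labels > n_classes):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    targets = np.zeros((labels.size, n_classes))
    targets[np.arange(labels.size), labels - 1] = 1.0
    return targets


def component_spectrum(activation: Sequence[float],
                       sampling_rate: float) -> np.ndarray:
    """70-band (1-70 Hz) power spectrum of a component activation.

    Power is estimated by an averaged periodogram (Bartlett: rectangular
    windows, no overlap, 0.5 Hz resolution) and integrated into 70
    contiguous 1-Hz bands centered on 1..70 Hz; band k collects the
    spectral mass in [k - 0.5, k + 0.5) Hz.
    """
    activation = np.asarray(activation, dtype=float)
    if sampling_rate < 140.0:
        raise ValueError("sampling_rate must be at least 140 Hz to resolve "
                         "content up to 70 Hz")
    if activation.ndim != 1 or activation.size < 2 * sampling_rate:
        raise ValueError("activation must be 1-D with length >= 2 * sampling_rate")
    nperseg = int(round(2 * sampling_rate))  # 0.5 Hz bins
    freqs, psd = sp_signal.welch(activation, fs=sampling_rate,
                                 window="boxcar", nperseg=nperseg,
                                 noverlap=0, detrend="constant")
    df = freqs[1] - freqs[0]
    bands = np.zeros(IC_SPECTRUM_BANDS)
    for k in range(1, IC_SPECTRUM_BANDS + 1):
        in_band = (freqs >= k - 0.5) & (freqs < k + 0.5)
        bands[k - 1] = psd[in_band].sum() * df
    return bands
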