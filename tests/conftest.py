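"""Shared fixtures: simulated datasets and trained classifiers.

The expensive end-to-end fits are session-scoped so the training-
protocol tests and the acceptance battery reuse the same models.
"""

from __future__ import annotations

import numpy as np
import pytest

import twolayer as tl
from twolayer.features import build_ic_matrix, build_tmaze_matrix

TMAZE_SIM_SEED = 11
TMAZE_TRAIN_SEED = 5
IC_SIM_SEED = 2
IC_TRAIN_SEED = 4


@pytest.fixture(scope="session")
def tmaze_dataset():
    """1000 simulated joystick trials (10 participants x 5 x 20)."""
    config = tl.TrajectorySimConfig(n_participants=10, trials_per_condition=20,
                                    seed=TMAZE_SIM_SEED)
    trials, labels = tl.simulate_tmaze_dataset(config)
    return trials, np.array(labels), config


@pytest.fixture(scope="session")
def tmaze_fit(tmaze_dataset):
    """Huang-sized network trained with SCG defaults on the trial set."""
    trials, labels, _ = tmaze_dataset
    X = build_tmaze_matrix(trials)
    config = tl.TrainConfig(algorithm="scg", seed=TMAZE_TRAIN_SEED,
                            max_epochs=300)
    model, history, split = tl.train_classifier(X, labels, config)
    return {"model": model, "history": history, "split": split,
            "X": X, "labels": labels, "config": config}


@pytest.fixture(scope="session")
def ic_dataset():
    """1632 simulated independent components (51 participants x 32)."""
    config = tl.ICSimConfig(seed=IC_SIM_SEED)
    components, kinds = tl.simulate_ic_dataset(config)
    labels = np.array([1 if c.label == "artifact" else 2 for c in components])
    return components, kinds, labels, config


@pytest.fixture(scope="session")
def ic_fit(ic_dataset):
    """Huang-sized network trained with SCG defaults on the components."""
    components, _, labels, _ = ic_dataset
    X = build_ic_matrix(components)
    config = tl.TrainConfig(algorithm="scg", seed=IC_TRAIN_SEED,
                            max_epochs=300)
    model, history, split = tl.train_classifier(X, labels, config)
    return {"model": model, "history": history, "split": split,
            "X": X, "labels": labels, "config": config}


def make_trial(x=None, y=None, participant_id=1, trial_index=1, condition=1):
    """Trial builder with zero-filled series by default."""
    from twolayer.records import TRAJECTORY_SAMPLES
    x = np.zeros(TRAJECTORY_SAMPLES) if x is None else np.asarray(x, dtype=float)
    y = np.zeros(TRAJECTORY_SAMPLES) if y is None else np.asarray(y, dtype=float)
    return tl.TrajectoryTrial(participant_id=participant_id,
                              trial_index=trial_index, condition=condition,
                              x=x, y=y)
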