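"""Delimited-text readers and writers for trials, components and labels.

Trajectory tables come in two layouts, autodetected from the header:

* long — columns participant, trial, condition, sample_index, x, y
  (one row per sample);
* wide — columns participant, trial, condition, x_0001..x_3000,
  y_0001..y_3000 (one row per trial).

Component tables are wide only: tc_0001..tc_1500, topo_01..topo_32,
f01..f70, pid and an optional label column.  All files are
tab-separated with a header row.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .records import (IC_SPECTRUM_BANDS, IC_TIMECOURSE_SAMPLES,
                      IC_TOPOGRAPHY_CHANNELS, TRAJECTORY_SAMPLES,
                      ICComponent, TrajectoryTrial)
from .rules import RuleParams

_X_COLS = [f"x_{i:04d}" for i in range(1, TRAJECTORY_SAMPLES + 1)]
_Y_COLS = [f"y_{i:04d}" for i in range(1, TRAJECTORY_SAMPLES + 1)]
_TC_COLS = [f"tc_{i:04d}" for i in range(1, IC_TIMECOURSE_SAMPLES + 1)]
_TOPO_COLS = [f"topo_{i:02d}" for i in range(1, IC_TOPOGRAPHY_CHANNELS + 1)]
_F_COLS = [f"f{i:02d}" for i in range(1, IC_SPECTRUM_BANDS + 1)]


def write_trials(trials: Iterable[TrajectoryTrial], path,
                 layout: str = "wide") -> None:
    """Write a trajectory table in wide or long layout (TSV)."""
    trials = list(trials)
    if layout == "wide":
        frame = pd.DataFrame({
            "participant": [t.participant_id for t in trials],
            "trial": [t.trial_index for t in trials],
            "condition": [t.condition for t in trials],
        })
        frame = pd.concat([
            frame,
            pd.DataFrame(np.array([t.x for t in trials]), columns=_X_COLS),
            pd.DataFrame(np.array([t.y for t in trials]), columns=_Y_COLS),
        ], axis=1)
    elif layout == "long":
        chunks = []
        for t in trials:
            chunks.append(pd.DataFrame({
                "participant": t.participant_id,
                "trial": t.trial_index,
                "condition": t.condition,
                "sample_index": np.arange(1, TRAJECTORY_SAMPLES + 1),
                "x": t.x, "y": t.y,
            }))
        frame = pd.concat(chunks, ignore_index=True)
    else:
        raise ValueError("layout must be 'wide' or 'long'")
    frame.to_csv(path, sep="\t", index=False)


def read_trials(path) -> list[TrajectoryTrial]:
    """Read a trajectory table; the layout is detected from the header."""
    frame = pd.read_csv(path, sep="\t")
    required = {"participant", "trial", "condition"}
    if not required.issubset(frame.columns):
        raise ValueError(f"trajectory table must contain columns {sorted(required)}")
    trials = []
    if "sample_index" in frame.columns:  # long layout
        keys = ["participant", "trial", "condition"]
        for (pid, trial, cond), group in frame.groupby(keys, sort=False):
            group = group.sort_values("sample_index")
            trials.append(TrajectoryTrial(
                participant_id=int(pid), trial_index=int(trial),
                condition=int(cond),
                x=group["x"].to_numpy(), y=group["y"].to_numpy()))
    else:  # wide layout
        for _, row in frame.iterrows():
            trials.append(TrajectoryTrial(
                participant_id=int(row["participant"]),
                trial_index=int(row["trial"]),
                condition=int(row["condition"]),
                x=row[_X_COLS].to_numpy(dtype=float),
                y=row[_Y_COLS].to_numpy(dtype=float)))
    return trials


def write_labels(trials: Sequence[TrajectoryTrial], labels: Sequence[int],
                 path) -> None:
    """Write a (participant, trial, condition, label) table."""
    pd.DataFrame({
        "participant": [t.participant_id for t in trials],
        "trial": [t.trial_index for t in trials],
        "condition": [t.condition for t in trials],
        "label": list(labels),
    }).to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "label" not in frame.columns:
        raise ValueError("labels table must contain a 'label' column")
    return frame


def write_components(components: Iterable[ICComponent], path) -> None:
    """Write a wide component table (TSV), including labels if present."""
    components = list(components)
    frame = pd.concat([
        pd.DataFrame(np.array([c.mean_timecourse for c in components]),
                     columns=_TC_COLS),
        pd.DataFrame(np.array([c.topography for c in components]),
                     columns=_TOPO_COLS),
        pd.DataFrame(np.array([c.spectrum for c in components]),
                     columns=_F_COLS),
    ], axis=1)
    frame["pid"] = [c.participant_id for c in components]
    if all(c.label is not None for c in components):
        frame["label"] = [c.label for c in components]
    frame.to_csv(path, sep="\t", index=False)


def read_components(path) -> list[ICComponent]:
    frame = pd.read_csv(path, sep="\t")
    components = []
    for _, row in frame.iterrows():
        components.append(ICComponent(
            mean_timecourse=row[_TC_COLS].to_numpy(dtype=float),
            topography=row[_TOPO_COLS].to_numpy(dtype=float),
            spectrum=row[_F_COLS].to_numpy(dtype=float),
            participant_id=int(row["pid"]),
            label=row["label"] if "label" in frame.columns else None))
    return components


def write_feature_matrix(X: np.ndarray, columns: Sequence[str], path) -> None:
    """Generic delimited feature matrix with named columns."""
    pd.DataFrame(np.asarray(X), columns=list(columns)).to_csv(
        path, sep="\t", index=False)


def read_feature_matrix(path) -> tuple[np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t")
    return frame.to_numpy(dtype=float), list(frame.columns)


def load_rule_params(path) -> RuleParams:
    """Read rule thresholds from a YAML mapping (missing keys default)."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    return RuleParams(**data)


def dump_manifest(config, seed: int, path) -> None:
    """Echo a simulation config plus its seed as YAML (reproducibility)."""
    payload = {"seed": seed}
    for key, value in vars(config).items():
        if isinstance(value, dict):
            payload[key] = {k: list(v) for k, v in value.items()}
        elif isinstance(value, tuple):
            payload[key] = list(value)
        else:
            payload[key] = value
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)
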