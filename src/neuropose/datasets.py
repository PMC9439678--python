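"""Per-neuron trial containers and tabular I/O.

A :class:`NeuronDataset` holds every completed trial for one neuron
across both tasks as a pandas ``DataFrame`` (one row per trial) plus an
optional list of spike-time arrays aligned row-by-row with the table.

Alignment conventions (1 ms resolution throughout):

* tilt-task spike times are relative to stimulus onset and span
  ``[-fixation_duration, stimulus_duration]``;
* saccade-task spike times are relative to saccade initiation.

``spike_count`` is the number of spikes inside the dataset's response
window (tilt task) or saccade analysis window (saccade task), so counts
and times are mutually consistent by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .design import TaskDesign

TRIAL_COLUMNS = [
    "neuron_id",
    "task",
    "block",
    "tilt",
    "slant",
    "distance_cm",
    "spike_count",
    "reported_tilt",
    "saccade_dir",
    "saccade_latency_ms",
]


@dataclass
class NeuronDataset:
    """All trials for one neuron, with optional spike trains.

    Parameters
    ----------
    neuron_id : str
    design : TaskDesign
    trials : DataFrame with :data:`TRIAL_COLUMNS`
    spike_times : per-trial arrays (ms) aligned with ``trials`` rows,
        or ``None`` entries for trials simulated counts-only.
    response_window : (start, stop) ms relative to stimulus onset over
        which tilt-task spike counts were taken.
    saccade_window : (start, stop) ms relative to saccade initiation.
    truth : ground-truth parameter record for simulated data.
    """

    neuron_id: str
    design: TaskDesign
    trials: pd.DataFrame
    spike_times: Optional[List[Optional[np.ndarray]]] = None
    response_window: Tuple[float, float] = (46.0, 1000.0)
    saccade_window: Tuple[float, float] = (-300.0, 0.0)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if self.spike_times is not None and len(self.spike_times) != len(self.trials):
            raise ValueError("spike_times must align with the trial table")

    def tilt_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["task"] == "tilt"]

    def saccade_trials(self) -> pd.DataFrame:
        return self.trials[self.trials["task"] == "saccade"]

    def frontoparallel_trials(self) -> pd.DataFrame:
        t = self.tilt_trials()
        return t[t["slant"] == 0.0]

    @property
    def n_blocks(self) -> int:
        return int(self.trials["block"].max()) + 1 if len(self.trials) else 0

    def rates(self, rows: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Firing rates (spikes/s) over the response window."""
        if rows is None:
            rows = self.tilt_trials()
        w0, w1 = self.response_window
        return rows["spike_count"].to_numpy(dtype=float) * 1000.0 / (w1 - w0)

    def spike_times_for(self, index: np.ndarray) -> list:
        if self.spike_times is None:
            raise ValueError("dataset was simulated without spike times")
        return [self.spike_times[i] for i in index]

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_csv(self, directory, stem: Optional[str] = None) -> dict:
        """Write trial table, spike-time long table, and truth sidecar.

        Returns a dict of written paths.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or self.neuron_id
        paths = {}
        trial_path = directory / f"{stem}_trials.csv"
        self.trials.to_csv(trial_path, index=False)
        paths["trials"] = trial_path
        if self.spike_times is not None:
            rows = []
            for trial_id, st in enumerate(self.spike_times):
                if st is None:
                    continue
                for t in np.asarray(st, dtype=float):
                    rows.append((self.neuron_id, trial_id, t))
            spikes = pd.DataFrame(rows, columns=["neuron_id", "trial_id", "t_ms"])
            spike_path = directory / f"{stem}_spikes.csv"
            spikes.to_csv(spike_path, index=False)
            paths["spikes"] = spike_path
        if self.truth is not None:
            truth_path = directory / f"{stem}_truth.json"
            truth_path.write_text(json.dumps(self.truth, indent=2, default=_jsonable))
            paths["truth"] = truth_path
        return paths


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_trials_csv(path) -> pd.DataFrame:
    """Read a trial table, validating the documented schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df["spike_count"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative spike_count at rows {list(bad[:5])}")
    lat = df["saccade_latency_ms"].dropna()
    if (lat <= 0).any():
        rows = list(df.index[df["saccade_latency_ms"] <= 0][:5])
        raise ValueError(f"{path}: non-positive saccade latency at rows {rows}")
    return df
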