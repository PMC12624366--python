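"""Epoched EEG container and HDF5 round-trip I/O.

An :class:`EpochArray` holds trials x channels x samples voltages (microvolts)
with a time axis in seconds (t = 0 at stimulus onset, half-open window) and
per-trial annotations (stimulus id, sequence index, target flag) aligned to a
sequence plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochArray", "read_epochs", "write_epochs"]


@dataclass
class EpochArray:
    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolts
    sampling_rate: float  # Hz
    time: np.ndarray  # seconds, len == n_samples
    channel_names: list[str]
    trials: pd.DataFrame  # columns: stimulus_id, sequence_index, is_target
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.time.shape[0]:
            raise ValueError("time axis length does not match data")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial annotations do not match data")
        if np.isnan(self.data).any():
            raise ValueError("epoch data contains missing values")
        self.trials = self.trials.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self, data: np.ndarray | None = None, **updates) -> "EpochArray":
        kwargs = dict(
            data=self.data.copy() if data is None else data,
            sampling_rate=self.sampling_rate,
            time=self.time.copy(),
            channel_names=list(self.channel_names),
            trials=self.trials.copy(),
            seed=self.seed,
            meta=dict(self.meta),
        )
        kwargs.update(updates)
        return EpochArray(**kwargs)

    def select_trials(self, mask) -> "EpochArray":
        mask = np.asarray(mask)
        return self.copy(
            data=self.data[mask], trials=self.trials.iloc[mask].copy()
        )

    def non_targets(self) -> "EpochArray":
        """Drop trials flagged as targets (excluded from every analysis)."""
        return self.select_trials(~self.trials["is_target"].to_numpy(bool))

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds); error outside."""
        if t < self.time[0] - 0.5 / self.sampling_rate or t > self.time[-1] + 0.5 / self.sampling_rate:
            raise ValueError(f"time {t} s outside epoch [{self.time[0]}, {self.time[-1]}]")
        return int(np.argmin(np.abs(self.time - t)))


def write_epochs(epochs: EpochArray, path) -> None:
    """Write an EpochArray to HDF5 plus a JSON sidecar (bit-exact round trip)."""
    path = str(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("time", data=epochs.time)
        labels = f.create_group("labels")
        labels.create_dataset(
            "stimulus_id",
            data=np.asarray(epochs.trials["stimulus_id"], dtype="S64"),
        )
        labels.create_dataset(
            "sequence_index", data=epochs.trials["sequence_index"].to_numpy(int)
        )
        labels.create_dataset(
            "is_target", data=epochs.trials["is_target"].to_numpy(bool)
        )
        f.attrs["sampling_rate"] = float(epochs.sampling_rate)
        if epochs.seed is not None:
            f.attrs["seed"] = int(epochs.seed)
        f.attrs["channel_names"] = json.dumps(list(epochs.channel_names))
    sidecar = {
        "sampling_rate": float(epochs.sampling_rate),
        "n_trials": int(epochs.n_trials),
        "n_channels": int(epochs.n_channels),
        "n_samples": int(epochs.n_samples),
        "seed": epochs.seed,
        "channel_names": list(epochs.channel_names),
        "meta": epochs.meta,
    }
    with open(path + ".json", "w") as f:
        json.dump(sidecar, f, indent=1, sort_keys=True)


def read_epochs(path) -> EpochArray:
    path = str(path)
    with h5py.File(path, "r") as f:
        for name in ("data", "time", "labels"):
            if name not in f:
                raise ValueError(f"epoch file {path} is missing dataset '{name}'")
        data = f["data"][()]
        time = f["time"][()]
        trials = pd.DataFrame(
            {
                "stimulus_id": [
                    s.decode() for s in f["labels/stimulus_id"][()]
                ],
                "sequence_index": f["labels/sequence_index"][()],
                "is_target": f["labels/is_target"][()].astype(bool),
            }
        )
        sampling_rate = float(f.attrs["sampling_rate"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        channel_names = json.loads(f.attrs["channel_names"])
    meta = {}
    try:
        with open(path + ".json") as fh:
            meta = json.load(fh).get("meta", {})
    except FileNotFoundError:
        pass
    return EpochArray(
        data=data,
        sampling_rate=sampling_rate,
        time=time,
        channel_names=channel_names,
        trials=trials,
        seed=seed,
        meta=meta,
    )
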