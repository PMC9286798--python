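"""Containers and on-disk formats.

Two portable formats are used throughout:

* ``EpochSet`` — epoched EEG (trial x channel x sample, microvolts) stored in
  an HDF5 container with datasets ``/data``, ``/channels``, ``/times_ms`` and
  root attributes ``srate_hz``, ``lock_event``, ``reference_state``.
* trial tables — per-trial behaviour, stored as a tab-separated file with
  columns ``trial_index, condition, rt_ms, outcome, target_duration_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("gain", "loss", "neutral")
TRIAL_COLUMNS = ["trial_index", "condition", "rt_ms", "outcome", "target_duration_ms"]


@dataclass
class EpochSet:
    """Epoched multichannel EEG.

    data
        Array of shape (n_trials, n_channels, n_samples), microvolts.
    channel_labels
        10-10 montage names, one per channel row.
    srate_hz
        Sampling rate of the epoch time grid.
    times_ms
        Sample times relative to the lock event (0 = event onset); strictly
        increasing with uniform spacing 1000/srate_hz.
    lock_event
        One of ``cue``, ``target``, ``feedback``.
    reference_state
        ``raw`` or ``average`` (after common average referencing).
    """

    data: np.ndarray
    channel_labels: list[str]
    srate_hz: float
    times_ms: np.ndarray
    lock_event: str = "cue"
    reference_state: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, channel, sample)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("sample axis does not match times_ms")
        dt = np.diff(self.times_ms)
        if self.times_ms.size > 1:
            step = 1000.0 / self.srate_hz
            if not np.all(dt > 0) or not np.allclose(dt, step, rtol=1e-6):
                raise ValueError("times_ms must increase uniformly at 1000/srate_hz")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(), times_ms=self.times_ms.copy(),
                       channel_labels=list(self.channel_labels))

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[np.asarray(index)])

    def channel_index(self, labels: list[str]) -> np.ndarray:
        lookup = {ch: i for i, ch in enumerate(self.channel_labels)}
        missing = [ch for ch in labels if ch not in lookup]
        if missing:
            raise KeyError(f"channel(s) not in montage: {missing}")
        return np.asarray([lookup[ch] for ch in labels])

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset(
                "channels", data=np.array(self.channel_labels, dtype="S")
            )
            f.create_dataset("times_ms", data=self.times_ms)
            f.attrs["srate_hz"] = self.srate_hz
            f.attrs["lock_event"] = self.lock_event
            f.attrs["reference_state"] = self.reference_state

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                channel_labels=[c.decode() for c in f["channels"][()]],
                srate_hz=float(f.attrs["srate_hz"]),
                times_ms=f["times_ms"][()],
                lock_event=str(f.attrs["lock_event"]),
                reference_state=str(f.attrs["reference_state"]),
            )


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing column(s): {missing}")
    bad = set(trials["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition(s): {sorted(bad)}")
    if not set(np.unique(trials["outcome"])) <= {-1, 1}:
        raise ValueError("outcome must be coded +1 (hit) / -1 (miss)")
    return trials


def write_trial_table(trials: pd.DataFrame, path) -> None:
    validate_trial_table(trials)
    trials.to_csv(path, sep="\t", index=False, na_rep="")


def read_trial_table(path) -> pd.DataFrame:
    trials = pd.read_csv(path, sep="\t")
    return validate_trial_table(trials)


@dataclass
class SlidingResult:
    """Output of a sliding-window discriminant analysis.

    Arrays are aligned on the window-center grid; windows that could not be
    evaluated (outside the epoch span, or fewer than 2 trials per class)
    carry ``valid=False`` and NaN records.
    """

    centers_ms: np.ndarray
    az: np.ndarray                 # LOO Az per window
    lam: np.ndarray                # selected shrinkage per window
    weights: np.ndarray            # (n_windows, n_channels) full-data w
    y: np.ndarray                  # (n_windows, n_trials) component amplitudes
    labels: np.ndarray             # per-trial class (bool, True = positive)
    valid: np.ndarray
    n_pos: int = 0
    n_neg: int = 0
    channel_labels: list[str] = field(default_factory=list)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("centers_ms", data=self.centers_ms)
            f.create_dataset("az", data=self.az)
            f.create_dataset("lambda", data=self.lam)
            f.create_dataset("weights", data=self.weights)
            f.create_dataset("y", data=self.y)
            f.create_dataset("labels", data=self.labels.astype(np.int8))
            f.create_dataset("valid", data=self.valid.astype(np.int8))
            f.create_dataset(
                "channels", data=np.array(self.channel_labels, dtype="S")
            )
            f.attrs["n_pos"] = self.n_pos
            f.attrs["n_neg"] = self.n_neg

    @classmethod
    def from_hdf5(cls, path) -> "SlidingResult":
        with h5py.File(path, "r") as f:
            return cls(
                centers_ms=f["centers_ms"][()],
                az=f["az"][()],
                lam=f["lambda"][()],
                weights=f["weights"][()],
                y=f["y"][()],
                labels=f["labels"][()].astype(bool),
                valid=f["valid"][()].astype(bool),
                n_pos=int(f.attrs["n_pos"]),
                n_neg=int(f.attrs["n_neg"]),
                channel_labels=[c.decode() for c in f["channels"][()]],
            )
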