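"""Core in-memory containers and their on-disk layouts.

The pipeline works on two containers: a continuous multichannel
:class:`Recording` and an epoched :class:`EpochSet` (trials x channels x
time).  Trial metadata travels separately as a pandas ``DataFrame`` (the
"trial table") with one row per keypress.

On disk, trial tables are CSV and epoch sets are HDF5 with datasets
``/data``, ``/times``, ``/labels``, ``/block`` and root attributes
``sfreq``, ``lock``, ``subject_id`` (plus a ``provenance`` list of the
processing steps applied, so a rerun with the same config can be checked
byte-for-byte).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

#: canonical finger labels: left/right index and middle fingers
FINGERS = ("LI", "LM", "RI", "RM")

#: trial-table columns written to / expected from CSV
TRIAL_COLUMNS = (
    "block", "cycle", "position", "key", "pressed", "finger",
    "rt", "correct", "onset",
)


@dataclass
class Recording:
    """Continuous multichannel signal: ``data`` is (n_channels, n_samples)."""

    data: np.ndarray
    sfreq: float
    first_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.first_time + np.arange(self.data.shape[1]) / self.sfreq


@dataclass
class EpochSet:
    """Epoched data: ``data`` is (n_trials, n_channels, n_times).

    ``times`` is seconds relative to the lock point (button press by
    default); ``labels`` holds one finger label per trial and ``block``
    the 1-based SRTT block index.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    labels: np.ndarray
    block: np.ndarray
    lock: str = "response"
    subject_id: str = "sim"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        self.block = np.asarray(self.block)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (trials x channels x times)")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length does not match data")
        if self.data.shape[0] != self.labels.size or self.data.shape[0] != self.block.size:
            raise ValueError("labels/block length does not match number of trials")
        if self.lock not in ("response", "stimulus"):
            raise ValueError(f"unknown lock point {self.lock!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select(self, mask_or_idx: np.ndarray, note: str | None = None) -> "EpochSet":
        """Return a new set with a subset of trials (alignment preserved)."""
        idx = np.asarray(mask_or_idx)
        prov = self.provenance + ([note] if note else [])
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            block=self.block[idx],
            provenance=prov,
        )

    def copy_with(self, **kw) -> "EpochSet":
        return replace(self, **kw)


def save_epochs_h5(path, x: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=x.data)
        f.create_dataset("times", data=x.times)
        f.create_dataset("labels", data=np.asarray(x.labels, dtype="S8"))
        f.create_dataset("block", data=np.asarray(x.block, dtype=np.int64))
        f.attrs["sfreq"] = x.sfreq
        f.attrs["lock"] = x.lock
        f.attrs["subject_id"] = x.subject_id
        f.attrs["provenance"] = "\n".join(x.provenance)


def load_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        prov = str(f.attrs.get("provenance", ""))
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            labels=f["labels"][()].astype(str),
            block=f["block"][()],
            lock=str(f.attrs["lock"]),
            subject_id=str(f.attrs.get("subject_id", "sim")),
            provenance=prov.split("\n") if prov else [],
        )


def save_trials_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))


def load_trials_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return table


def epochs_to_mne(x: EpochSet):
    """Convert to :class:`mne.EpochsArray` (misc channels, synthetic layout)."""
    import mne

    info = mne.create_info(
        [f"CH{i:03d}" for i in range(x.n_channels)], x.sfreq, ch_types="misc"
    )
    codes = {lab: i for i, lab in enumerate(FINGERS)}
    events = np.column_stack(
        [
            np.arange(x.n_trials) * (x.n_times + 1),
            np.zeros(x.n_trials, dtype=int),
            np.array([codes[str(l)] for l in x.labels]),
        ]
    )
    return mne.EpochsArray(
        x.data, info, events=events, tmin=float(x.times[0]), event_id=codes,
        verbose="error",
    )
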