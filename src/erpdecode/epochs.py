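"""Epoch container: labeled multi-channel time-locked trials plus metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .channels import CHANNELS

#: Metadata columns every EpochSet carries (one row per trial).
META_COLUMNS = (
    "subject",
    "condition",
    "phase",
    "selection",
    "sequence",
    "stimulus",
    "is_target",
    "onset_ms",
)


@dataclass
class EpochSet:
    """Time-locked trials: ``data`` is (n_trials, n_channels, n_times) in µV.

    ``times`` is the time axis in ms relative to stimulus onset (−200..790 at
    100 Hz under the default half-open [−200, 800) window). ``meta`` has one
    row per trial with the columns in :data:`META_COLUMNS`.
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    meta: pd.DataFrame
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel list")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis does not match times vector")
        if len(self.meta) != self.data.shape[0]:
            raise ValueError("metadata length must equal trial count")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        self.meta = self.meta.reset_index(drop=True)

    # ------------------------------------------------------------------ basic
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def __len__(self) -> int:
        return self.n_trials

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def select(self, mask: np.ndarray | None = None, **filters) -> "EpochSet":
        """Subset trials by boolean mask and/or metadata equality filters.

        ``epochs.select(condition="passive", is_target=True)``; a tuple/list
        filter value selects membership.
        """
        m = np.ones(self.n_trials, dtype=bool) if mask is None else np.asarray(mask)
        for col, val in filters.items():
            if isinstance(val, (list, tuple, set, np.ndarray)):
                m &= self.meta[col].isin(list(val)).to_numpy()
            else:
                m &= (self.meta[col] == val).to_numpy()
        return EpochSet(
            self.data[m], self.times, self.sfreq, self.meta.loc[m], self.channels
        )

    def average(self) -> np.ndarray:
        """Grand-average ERP (n_channels, n_times) over all trials."""
        if self.n_trials == 0:
            raise ValueError("cannot average an empty EpochSet")
        return self.data.mean(axis=0)

    @staticmethod
    def concatenate(parts: list["EpochSet"]) -> "EpochSet":
        first = parts[0]
        for p in parts[1:]:
            if not np.array_equal(p.times, first.times) or p.channels != first.channels:
                raise ValueError("cannot concatenate incompatible EpochSets")
        return EpochSet(
            np.concatenate([p.data for p in parts], axis=0),
            first.times,
            first.sfreq,
            pd.concat([p.meta for p in parts], ignore_index=True),
            first.channels,
        )

    # ------------------------------------------------------------------- I/O
    def save(self, path) -> None:
        """Write the hierarchical container: /data, /times, /metadata."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("times", data=self.times)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["channels"] = list(self.channels)
            g = f.create_group("metadata")
            for col in self.meta.columns:
                vals = self.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            sfreq = float(f.attrs["sfreq"])
            channels = tuple(
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f.attrs["channels"]
            )
            meta = {}
            for col in f["metadata"]:
                vals = f["metadata"][col][()]
                if vals.dtype.kind == "S":
                    vals = np.char.decode(vals.astype("S"))
                meta[col] = vals
        return cls(data, times, sfreq, pd.DataFrame(meta), channels)

    def to_mne(self):
        """Export as :class:`mne.EpochsArray` (requires the ``mne`` extra)."""
        try:
            import mne
        except ImportError as err:  # pragma: no cover
            raise ImportError("install erpdecode[mne] for MNE export") from err
        info = mne.create_info(list(self.channels), self.sfreq, ch_types="eeg")
        events = np.column_stack(
            [
                np.arange(self.n_trials),
                np.zeros(self.n_trials, dtype=int),
                self.meta["is_target"].astype(int).to_numpy() + 1,
            ]
        )
        return mne.EpochsArray(
            self.data * 1e-6,  # µV -> V
            info,
            events=events,
            tmin=self.times[0] / 1000.0,
            event_id={"nontarget": 1, "target": 2},
            metadata=self.meta.copy(),
            verbose="error",
        )


def count_trials(epochs: EpochSet) -> pd.DataFrame:
    """Target / non-target trial counts per (condition, phase).

    Returns a DataFrame indexed by (condition, phase) with columns
    ``n_target`` and ``n_nontarget``; empty input yields an empty frame.
    """
    if epochs.n_trials == 0:
        return pd.DataFrame(
            columns=["n_target", "n_nontarget"],
            index=pd.MultiIndex.from_arrays([[], []], names=["condition", "phase"]),
        )
    grp = epochs.meta.groupby(["condition", "phase"])["is_target"]
    out = pd.DataFrame(
        {
            "n_target": grp.sum().astype(int),
            "n_nontarget": (grp.count() - grp.sum()).astype(int),
        }
    )
    return out
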