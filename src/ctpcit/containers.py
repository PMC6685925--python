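"""Core data containers shared across the pipeline.

The pipeline operates on epoched multi-channel EEG.  :class:`EpochSet` is the
canonical container: a ``(n_epochs, n_channels, n_samples)`` array in microvolts
with a sampling rate, channel labels, the epoch start time relative to stimulus
onset, and an aligned per-trial event table.  :class:`Recording` holds a
continuous multi-channel signal for the (optional) continuous-input path.

On disk an :class:`EpochSet` is a directory with ``data.npy``, a JSON sidecar
(``meta.json``: srate, channels, window) and ``events.csv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "Recording"]


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x samples (microvolts) plus events.

    Parameters
    ----------
    data : ndarray, shape (n_epochs, n_channels, n_samples)
        Signal in microvolts.
    srate : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel labels (e.g. ``Pz``, ``TP9``, ``VEOGu``).
    tmin_ms : float
        Time of sample 0 relative to stimulus onset, in ms (e.g. ``-100``).
    events : pandas.DataFrame
        One row per epoch, aligned with axis 0 of ``data``.  Typical columns:
        ``trial_index, block, category, role, item, correct, rt_ms``.
    """

    data: np.ndarray
    srate: float
    ch_names: list[str]
    tmin_ms: float
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("ch_names length does not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if len(self.events) == 0:
            self.events = pd.DataFrame(index=range(self.data.shape[0]))
        if len(self.events) != self.data.shape[0]:
            raise ValueError("event table row count must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times relative to stimulus onset, in ms."""
        return self.tmin_ms + np.arange(self.n_samples) * 1000.0 / self.srate

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def channel(self, name: str) -> np.ndarray:
        """Return (n_epochs, n_samples) view of one channel."""
        return self.data[:, self.channel_index(name), :]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset epochs by a boolean mask or integer index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            srate=self.srate,
            ch_names=list(self.ch_names),
            tmin_ms=self.tmin_ms,
            events=self.events.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
        )

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.srate, list(self.ch_names),
                        self.tmin_ms, self.events.copy())

    # -- serialization ---------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "data.npy", self.data)
        meta = {"srate": self.srate, "ch_names": self.ch_names, "tmin_ms": self.tmin_ms}
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        self.events.to_csv(d / "events.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        return cls(
            data=np.load(d / "data.npy"),
            srate=meta["srate"],
            ch_names=list(meta["ch_names"]),
            tmin_ms=meta["tmin_ms"],
            events=pd.read_csv(d / "events.csv"),
        )


@dataclass
class Recording:
    """Continuous multi-channel signal with stimulus events.

    ``events`` needs an ``onset_sample`` column (sample index of stimulus
    onset); any further columns are carried into epochs on extraction.
    """

    data: np.ndarray
    srate: float
    ch_names: list[str]
    events: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length does not match data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]
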