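"""Trial x channel x time epoch container with an HDF5 round-trip.

The on-disk schema is fixed: datasets ``/data`` (trials x channels x samples,
float64), ``/time_ms`` (samples,), ``/channels`` (variable-length UTF-8), and
root attributes ``fs_hz``, ``hand``, ``timepoint``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

VALID_TIMEPOINTS = ("pre", "post", "")


@dataclass
class EpochSet:
    """Evoked-response epochs around a TMS trigger.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in µV (EEG) or mV (EMG).
    time_ms : ndarray, shape (n_samples,)
        Sample times relative to the trigger, strictly increasing.
    channels : list of str
        10-10 channel names for EEG; e.g. ``["FDI"]`` for EMG.
    fs_hz : float
        Sampling rate.
    hand : str
        ``"left"`` / ``"right"`` (or empty).
    timepoint : str
        ``"pre"`` or ``"post"`` relative to tDCS.
    """

    data: np.ndarray
    time_ms: np.ndarray
    channels: list[str]
    fs_hz: float
    hand: str = ""
    timepoint: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("sample count mismatch")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {VALID_TIMEPOINTS}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.time_ms.copy(), list(self.channels),
            self.fs_hz, self.hand, self.timepoint, dict(self.meta),
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset(
                "channels",
                data=np.array(self.channels, dtype=h5py.string_dtype("utf-8")),
            )
            f.attrs["fs_hz"] = float(self.fs_hz)
            f.attrs["hand"] = self.hand
            f.attrs["timepoint"] = self.timepoint

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                time_ms=f["time_ms"][()],
                channels=[c.decode() if isinstance(c, bytes) else str(c)
                          for c in f["channels"][()]],
                fs_hz=float(f.attrs["fs_hz"]),
                hand=str(f.attrs.get("hand", "")),
                timepoint=str(f.attrs.get("timepoint", "")),
            )
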