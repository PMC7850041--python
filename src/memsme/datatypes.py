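"""Core data containers shared by every analysis stage.

Tabular data (events, electrodes, cohort covariates) live in pandas
DataFrames with a validated schema; epoched voltage data live in
:class:`EpochTensor`, a thin wrapper around an ``items x channels x
samples`` ndarray that carries the sampling rate, the epoch window
relative to item onset and the width of the wavelet buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Columns required of an events table (one row per studied item).
EVENTS_COLUMNS = [
    "subject",
    "session",
    "task_variant",
    "list",
    "serial_position",
    "item",
    "category",
    "recalled",
    "output_position",
]

#: Columns required of an electrode table (one row per channel).
ELECTRODE_COLUMNS = ["channel", "region", "excluded"]

TASK_VARIANTS = ("unrelated", "categorized")

DEFAULT_REGIONS = ("frontal", "MTL", "LTC", "parietal")


class SchemaError(ValueError):
    """Raised when a table violates its schema or an invariant."""


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an events table and return it unchanged.

    Checks column presence, serial-position range, the recalled /
    output-position contract (an output position is present iff the item
    was recalled) and that output positions within each list form a
    contiguous ranking ``1..k``.
    """
    missing = [c for c in EVENTS_COLUMNS if c not in events.columns]
    if missing:
        raise SchemaError(f"events table missing columns: {missing}")
    if len(events) == 0:
        raise SchemaError("events table is empty")
    sp = events["serial_position"]
    if sp.min() < 1:
        raise SchemaError("serial_position must be >= 1")
    bad_variant = set(events["task_variant"].unique()) - set(TASK_VARIANTS)
    if bad_variant:
        raise SchemaError(f"unknown task_variant values: {sorted(bad_variant)}")
    recalled = events["recalled"].astype(bool)
    has_out = events["output_position"].notna()
    if (recalled != has_out).any():
        row = int(np.flatnonzero(recalled != has_out)[0])
        raise SchemaError(
            f"row {row}: output_position must be present iff recalled is true"
        )
    for (subj, sess, lst), grp in events.groupby(["subject", "session", "list"]):
        out = np.sort(grp.loc[grp["recalled"].astype(bool), "output_position"].to_numpy())
        k = len(out)
        if k and not np.array_equal(out, np.arange(1, k + 1)):
            raise SchemaError(
                f"list {subj}/{sess}/{lst}: output positions are not a 1..{k} ranking"
            )
    return events


def validate_electrodes(electrodes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ELECTRODE_COLUMNS if c not in electrodes.columns]
    if missing:
        raise SchemaError(f"electrode table missing columns: {missing}")
    if electrodes["channel"].duplicated().any():
        raise SchemaError("duplicate channel labels in electrode table")
    return electrodes


@dataclass
class EpochTensor:
    """Epoched multichannel voltage, ``items x channels x samples``.

    Parameters
    ----------
    data : ndarray, shape (n_items, n_channels, n_samples)
        Voltage in arbitrary units.
    fs : float
        Sampling rate in samples/s.
    tmin : float
        Time of the first sample relative to item onset, in seconds
        (negative when the epoch starts before onset).  The stored
        window *includes* the wavelet buffer.
    buffer : float
        Width in seconds of the mirrored/continued padding at each end
        of the epoch, kept so wavelet edge artefacts can be trimmed.
    channels : list of str
        Channel labels aligned with axis 1.
    """

    data: np.ndarray
    fs: float
    tmin: float
    buffer: float = 0.0
    channels: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise SchemaError("epoch data must be items x channels x samples")
        if not self.channels:
            self.channels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channels) != self.data.shape[1]:
            raise SchemaError("channel labels do not match channel axis")

    @property
    def n_items(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times relative to item onset, in seconds."""
        return self.tmin + np.arange(self.n_samples) / self.fs

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean sample mask for the closed window ``[start, end]`` s."""
        t = self.times
        return (t >= start - 0.5 / self.fs) & (t <= end + 0.5 / self.fs)

    def trim_buffer(self) -> "EpochTensor":
        """Drop the buffer samples at both ends."""
        if self.buffer <= 0:
            return self
        n = int(round(self.buffer * self.fs))
        return replace(
            self,
            data=self.data[:, :, n : self.n_samples - n],
            tmin=self.tmin + self.buffer,
            buffer=0.0,
        )

    def select_channels(self, keep: np.ndarray) -> "EpochTensor":
        keep = np.asarray(keep)
        return replace(
            self,
            data=self.data[:, keep, :],
            channels=[self.channels[i] for i in keep],
        )


def check_alignment(events: pd.DataFrame, epochs: EpochTensor) -> None:
    """Events rows and the epoch item axis must align 1:1."""
    if len(events) != epochs.n_items:
        raise SchemaError(
            f"events has {len(events)} rows but epochs has {epochs.n_items} items"
        )
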