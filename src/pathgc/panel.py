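"""Multichannel time-series container.

A :class:`TimeSeriesPanel` holds a T x n matrix of observations (rows are
time points, columns are channels -- e.g. fMRI ROI signals), channel labels
and, optionally, the sampling interval in seconds (the fMRI TR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["TimeSeriesPanel"]


@dataclass
class TimeSeriesPanel:
    """A T x n multichannel time series.

    Parameters
    ----------
    values : array-like, shape (T, n)
        Observations; rows are time points, columns are channels. Must be
        finite.
    channel_labels : list of str, optional
        One label per channel; defaults to ``ch1 .. chn``.
    sampling_interval_s : float, optional
        Time between consecutive rows, in seconds (the TR for fMRI-like
        data). ``None`` when the sampling rate is irrelevant.
    """

    values: np.ndarray
    channel_labels: list[str] = field(default=None)  # type: ignore[assignment]
    sampling_interval_s: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2:
            raise InputError(f"panel values must be 2-D, got shape {values.shape}")
        if values.shape[0] < 1:
            raise InputError("panel must contain at least one time point")
        if not np.all(np.isfinite(values)):
            t, c = np.argwhere(~np.isfinite(values))[0]
            raise InputError(f"non-finite value at row {t + 1}, channel {c + 1}")
        self.values = values
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i + 1}" for i in range(values.shape[1])]
        else:
            self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != values.shape[1]:
            raise InputError(
                f"{len(self.channel_labels)} labels for {values.shape[1]} channels"
            )
        if self.sampling_interval_s is not None:
            self.sampling_interval_s = float(self.sampling_interval_s)
            if self.sampling_interval_s <= 0:
                raise InputError("sampling_interval_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given as integer index or label."""
        if isinstance(channel, str):
            try:
                return self.channel_labels.index(channel)
            except ValueError:
                raise InputError(f"unknown channel label {channel!r}") from None
        idx = int(channel)
        if not -self.n_channels <= idx < self.n_channels:
            raise InputError(f"channel index {idx} out of range")
        return idx % self.n_channels

    def select(self, channels) -> "TimeSeriesPanel":
        """Sub-panel restricted to the given channels (indices or labels)."""
        idx = [self.channel_index(c) for c in channels]
        return TimeSeriesPanel(
            self.values[:, idx],
            [self.channel_labels[i] for i in idx],
            self.sampling_interval_s,
        )

    def centered(self) -> "TimeSeriesPanel":
        """Copy with per-channel means removed."""
        return TimeSeriesPanel(
            self.values - self.values.mean(axis=0),
            list(self.channel_labels),
            self.sampling_interval_s,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channel_labels)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, sampling_interval_s: float | None = None
    ) -> "TimeSeriesPanel":
        return cls(frame.to_numpy(dtype=float), [str(c) for c in frame.columns],
                   sampling_interval_s)
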