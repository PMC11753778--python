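"""Uniformly sampled time series, the signal currency of the package.

Every stimulus envelope, filter kernel and detector trace is a
:class:`TimeSeries`: a start time, a sample rate and a 1-D array of
finite values. Keeping the grid explicit lets downstream stages check
alignment instead of silently broadcasting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Sample values (arbitrary intensity units). Must be finite.
    sample_rate : float
        Sampling rate in Hz, strictly positive.
    start_time : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be positive")

    # -- grid helpers -------------------------------------------------
    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) * self.dt

    def __len__(self) -> int:
        return len(self.values)

    def same_grid(self, other: "TimeSeries", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.sample_rate, other.sample_rate, rtol=rtol)
            and np.isclose(self.start_time, other.start_time, rtol=rtol, atol=1e-12)
        )

    def require_same_grid(self, other: "TimeSeries") -> None:
        if not self.same_grid(other):
            raise ValueError(
                "time series are not on the same grid "
                f"(n={len(self)}/{len(other)}, fs={self.sample_rate}/{other.sample_rate}, "
                f"t0={self.start_time}/{other.start_time})"
            )

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Return a new series on the same grid with different values."""
        return TimeSeries(values=values, sample_rate=self.sample_rate, start_time=self.start_time)

    def to_csv(self, path) -> None:
        """Write (time, value) rows; two-column plain text for inspection."""
        np.savetxt(path, np.column_stack([self.times, self.values]), delimiter=",", header="time,value", comments="")
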