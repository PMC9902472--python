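"""Core containers shared by every analysis stage.

Conventions used throughout the package:

* all times are in seconds, 0-based;
* windows are half-open ``[start, end)``;
* vigilance states are labelled ``"W"`` (wake), ``"N"`` (NREM sleep) and
  ``"R"`` (REM sleep);
* hypnograms are sequences of fixed-length scoring epochs (5 s by default,
  the standard rodent scoring resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical vigilance-state labels, in display order.
STATES: tuple[str, ...] = ("W", "N", "R")

#: Long names used in reports.
STATE_NAMES: dict[str, str] = {"W": "Wake", "N": "NREM", "R": "REM"}

#: Units a trace can carry, in pipeline order.
TRACE_UNITS: tuple[str, ...] = (
    "raw_F",
    "dFF",
    "zscore",
    "norm_zscore",
    "detrended",
)


@dataclass
class Hypnogram:
    """A scored vigilance-state sequence on a fixed epoch grid.

    Parameters
    ----------
    labels : ndarray of str
        One label per epoch, each in :data:`STATES`.
    epoch_len : float
        Epoch length in seconds (5 s for rodent polysomnography).
    start_time : float
        Session time of the first epoch's left edge, seconds.
    """

    labels: np.ndarray
    epoch_len: float = 5.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.labels.size == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def epoch_starts(self) -> np.ndarray:
        return self.start_time + self.epoch_len * np.arange(self.n_epochs)

    def state_at(self, t: np.ndarray | float) -> np.ndarray:
        """Vectorised state lookup; times outside the span raise."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.floor((t - self.start_time) / self.epoch_len).astype(int)
        if np.any((idx < 0) | (idx >= self.n_epochs)):
            raise ValueError("time outside hypnogram span")
        return self.labels[idx]

    def mask_for_samples(self, times: np.ndarray, state: str) -> np.ndarray:
        """Boolean mask of the sample times falling in epochs of ``state``.

        Sample times outside the hypnogram span are masked out (False)
        rather than raising, so traces may slightly overhang the scoring.
        """
        times = np.asarray(times, dtype=float)
        idx = np.floor((times - self.start_time) / self.epoch_len).astype(int)
        inside = (idx >= 0) & (idx < self.n_epochs)
        out = np.zeros(times.shape, dtype=bool)
        out[inside] = self.labels[idx[inside]] == state
        return out


@dataclass
class Trace:
    """A uniformly sampled single-channel signal with a declared unit."""

    values: np.ndarray
    fs: float
    t0: float = 0.0
    unit: str = "raw_F"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.unit not in TRACE_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {TRACE_UNITS}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def index_of(self, t: float) -> int:
        """Nearest sample index for session time ``t`` (clipped to range)."""
        return int(np.clip(round((t - self.t0) * self.fs), 0, self.n - 1))

    def slice_time(self, start: float, end: float) -> "Trace":
        """Samples with t in the half-open window ``[start, end)``."""
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end - self.t0) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n)
        if i1 <= i0:
            raise ValueError("empty time slice")
        return replace(self, values=self.values[i0:i1], t0=self.t0 + i0 / self.fs)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float), unit=unit or self.unit)


@dataclass
class Event:
    """A single detected transient.

    ``peak_amp`` is measured relative to the pre-peak local baseline (the
    minimum of the trace over the approach to the peak), onset/offset are the
    10%-of-amplitude crossings, ``baseline`` is the mean of the signal over
    the 100 s preceding the onset, and ``auc`` integrates the
    baseline-subtracted signal over [onset, offset].
    """

    peak_time: float
    peak_amp: float
    onset: float = np.nan
    offset: float = np.nan
    auc: float = np.nan
    baseline: float = np.nan
    truncated: bool = False

    def validate(self) -> None:
        if np.isfinite(self.onset) and np.isfinite(self.offset):
            if not (self.onset <= self.peak_time <= self.offset):
                raise ValueError("event onset/peak/offset out of order")


@dataclass
class EventSet:
    """Detected transients of one trace, in time order."""

    events: list[Event] = field(default_factory=list)
    threshold: float = np.nan
    sd: float = np.nan

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events], dtype=float)

    @property
    def peak_amps(self) -> np.ndarray:
        return np.array([e.peak_amp for e in self.events], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset for e in self.events], dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([e.offset for e in self.events], dtype=float)

    @property
    def aucs(self) -> np.ndarray:
        return np.array([e.auc for e in self.events], dtype=float)
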