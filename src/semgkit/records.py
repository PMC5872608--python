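"""Core in-memory containers for multichannel surface-EMG data.

A :class:`SignalRecord` holds a channels-by-samples matrix in millivolts
together with its time base and acquisition metadata.  Downstream stages
exchange :class:`EnvelopeSignal` (per-sample amplitude estimate),
:class:`ActivityMask` (per-sample "movement is happening" logic signal),
:class:`AnalysisWindow` (one fixed-length window of samples) and
:class:`FeatureTrial` (the feature vector computed from one window).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .errors import ParameterError

DEFAULT_FS = 250.0  # Hz; the acquisition rate of the protocol being emulated
N_CHANNELS = 8


def default_channel_names(n: int) -> list[str]:
    return [f"CH{i + 1}" for i in range(n)]


@dataclass
class SignalRecord:
    """Multichannel time series in millivolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in mV.
    fs
        Sampling rate in Hz.
    time
        Time vector in seconds, length ``n_samples``, strictly increasing
        with step approximately ``1/fs``.
    channel_names
        One name per channel, in row order.
    meta
        Free-form acquisition metadata (subject id, movement label,
        session index, trial kind: ``volitional`` | ``fes`` | ``combined``).
    """

    data: np.ndarray
    fs: float
    time: np.ndarray | None = None
    channel_names: list[str] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if self.time is None:
            self.time = np.arange(self.n_samples) / self.fs
        else:
            self.time = np.asarray(self.time, dtype=float)
        if self.channel_names is None:
            self.channel_names = default_channel_names(self.n_channels)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if len(self.time) != self.n_samples:
            raise ParameterError(
                f"time vector length {len(self.time)} != sample count {self.n_samples}"
            )
        if len(self.channel_names) != self.n_channels:
            raise ParameterError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )
        if self.n_samples >= 2:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ParameterError("time vector is not strictly increasing")
            if not np.allclose(steps, 1.0 / self.fs, rtol=1e-6, atol=1e-12):
                raise ParameterError(
                    "time vector step is inconsistent with the sampling rate"
                )

    def copy_with(self, data: np.ndarray) -> "SignalRecord":
        """New record sharing this record's time base and metadata."""
        return SignalRecord(
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            time=self.time.copy(),
            channel_names=list(self.channel_names),
            meta=dict(self.meta),
        )

    def slice_samples(self, start: int, stop: int) -> "SignalRecord":
        """Sub-record over the half-open sample range ``[start, stop)``."""
        if not (0 <= start <= stop <= self.n_samples):
            raise ParameterError(f"sample range [{start}, {stop}) outside record")
        return SignalRecord(
            data=self.data[:, start:stop].copy(),
            fs=self.fs,
            time=self.time[start:stop].copy(),
            channel_names=list(self.channel_names),
            meta=dict(self.meta),
        )


@dataclass
class EnvelopeSignal:
    """Low-frequency amplitude envelope of a record.

    ``values`` is the across-channel mean envelope (nonnegative, mV) used
    for activity detection; ``per_channel`` keeps the individual channel
    envelopes, aligned 1:1 with the source record's samples.
    """

    values: np.ndarray
    fs: float
    per_channel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ParameterError("envelope values must be nonnegative")

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclass
class ActivityMask:
    """Per-sample logic signal marking detected muscle activity.

    ``segments`` lists half-open ``(start, stop)`` sample intervals that are
    disjoint, sorted, and consistent with ``active``.
    """

    active: np.ndarray
    fs: float
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active, dtype=bool)
        if not self.segments:
            self.segments = segments_from_bool(self.active)
        self._check_consistency()

    def _check_consistency(self) -> None:
        rebuilt = np.zeros_like(self.active)
        prev_stop = -1
        for start, stop in self.segments:
            if not (0 <= start < stop <= len(self.active)):
                raise ParameterError(f"segment ({start}, {stop}) outside mask")
            if start <= prev_stop:
                raise ParameterError("segments overlap or are unsorted")
            rebuilt[start:stop] = True
            prev_stop = stop
        if not np.array_equal(rebuilt, self.active):
            raise ParameterError("segments inconsistent with the active array")

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def jaccard(self, other: np.ndarray) -> float:
        """Per-sample Jaccard overlap with another boolean mask."""
        other = np.asarray(other, dtype=bool)
        union = np.logical_or(self.active, other).sum()
        if union == 0:
            return 1.0
        inter = np.logical_and(self.active, other).sum()
        return float(inter / union)


def segments_from_bool(active: np.ndarray) -> list[tuple[int, int]]:
    """Half-open run intervals of ``True`` in a boolean array."""
    active = np.asarray(active, dtype=bool)
    if active.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], active.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class AnalysisWindow:
    """One fixed-length analysis window cut from an active segment.

    ``samples`` has shape ``(n_channels, n)`` in mV; ``start_sample``
    indexes the window's first sample in the source record.
    """

    samples: np.ndarray
    window_length_s: float
    start_sample: int
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.n < 2:
            raise ParameterError("analysis window needs at least 2 samples")

    @property
    def n(self) -> int:
        return self.samples.shape[1]

    def channel(self, i: int) -> np.ndarray:
        return self.samples[i]


@dataclass
class FeatureTrial:
    """Feature vector of one analysis window, with its movement label.

    ``values`` is ordered channel-major: all selected features of the first
    selected channel, then the next channel, and so on.  With all 7 features
    over 8 channels the vector has 56 entries.
    """

    values: np.ndarray
    label: int
    feature_names: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.feature_names):
            raise ParameterError("feature vector and names disagree in length")


def as_trial_matrix(trials: Sequence[FeatureTrial]) -> tuple[np.ndarray, np.ndarray]:
    """Stack trials into an ``(n_trials, n_features)`` matrix plus labels."""
    if not trials:
        raise ParameterError("no trials to stack")
    names = trials[0].feature_names
    for t in trials:
        if t.feature_names != names:
            raise ParameterError("trials have inconsistent feature layouts")
    X = np.vstack([t.values for t in trials])
    y = np.array([t.label for t in trials], dtype=int)
    return X, y
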