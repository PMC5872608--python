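"""Windowing and time-domain sEMG features.

The seven classic features — MAV, WL, ZC, SD, IAV, V, SSC — plus RMS, all
computed per channel on fixed-length windows cut from detected-active
segments with fractional overlap.  Conventions:

* WL sums ``|x_i - x_{i-1}|`` over the ``n - 1`` adjacent pairs.
* ZC counts strict sign oppositions of adjacent samples; a zero sample
  never contributes.
* SSC counts interior local extrema, i.e. samples strictly above or
  strictly below both neighbours.
* SD and V use the ``n - 1`` (sample) normalization; V = SD² exactly.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import RunConfig
from .errors import ParameterError
from .records import ActivityMask, AnalysisWindow, FeatureTrial, SignalRecord

logger = logging.getLogger(__name__)


def mav(x: np.ndarray) -> float:
    """Mean absolute value: (1/n) Σ|x_i|."""
    x = _as_window(x, 1)
    return float(np.mean(np.abs(x)))


def wl(x: np.ndarray) -> float:
    """Waveform length: Σ|x_i − x_{i−1}| over adjacent pairs."""
    x = _as_window(x, 2)
    return float(np.sum(np.abs(np.diff(x))))


def zc(x: np.ndarray) -> float:
    """Zero crossings: adjacent pairs with strictly opposite signs."""
    x = _as_window(x, 2)
    a, b = x[:-1], x[1:]
    return float(np.count_nonzero((a > 0) & (b < 0) | (a < 0) & (b > 0)))


def sd(x: np.ndarray) -> float:
    """Sample standard deviation (n − 1 normalization)."""
    x = _as_window(x, 2)
    return float(np.std(x, ddof=1))


def iav(x: np.ndarray) -> float:
    """Integral of absolute value: Σ|x_i| (= n · MAV)."""
    x = _as_window(x, 1)
    return float(np.sum(np.abs(x)))


def variance(x: np.ndarray) -> float:
    """Sample variance (n − 1 normalization); equals sd(x)² exactly."""
    return sd(x) ** 2


def ssc(x: np.ndarray) -> float:
    """Slope-sign changes: interior samples that are strict local extrema."""
    x = _as_window(x, 3)
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return float(np.count_nonzero(left * right > 0))


def rms(x: np.ndarray) -> float:
    """Root mean square: sqrt((1/n) Σ x_i²)."""
    x = _as_window(x, 1)
    return float(np.sqrt(np.mean(x**2)))


FEATURE_FUNCTIONS = {
    "MAV": mav,
    "WL": wl,
    "ZC": zc,
    "SD": sd,
    "IAV": iav,
    "V": variance,
    "SSC": ssc,
    "RMS": rms,
}


def _as_window(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_len:
        raise ParameterError(f"window of {len(x)} samples; need at least {min_len}")
    return x


def segment_windows(
    record: SignalRecord,
    mask: ActivityMask,
    window_length_s: float,
    overlap: float,
) -> list[AnalysisWindow]:
    """Cut fully-contained overlapping windows from each active segment.

    Within a segment, windows start at multiples of
    ``step = round((1 − overlap) · n)`` samples (at least 1).  Segments
    shorter than one window contribute nothing; if no segment fits a
    window at all, an empty list is returned with a warning.
    """
    if not 0 <= overlap < 1:
        raise ParameterError(f"overlap must lie in [0, 1), got {overlap}")
    n = round(window_length_s * record.fs)
    if n < 2:
        raise ParameterError(
            f"window of {window_length_s} s is under 2 samples at {record.fs} Hz"
        )
    step = max(1, round((1.0 - overlap) * n))
    windows: list[AnalysisWindow] = []
    for start, stop in mask.segments:
        length = stop - start
        if length < n:
            continue
        count = (length - n) // step + 1
        for j in range(count):
            s = start + j * step
            windows.append(
                AnalysisWindow(
                    samples=record.data[:, s : s + n].copy(),
                    window_length_s=window_length_s,
                    start_sample=s,
                    fs=record.fs,
                )
            )
    if not windows:
        logger.warning(
            "no window of %.3g s fits any of %d active segments",
            window_length_s,
            len(mask.segments),
        )
    return windows


def trial_feature_names(features: list[str], channel_names: list[str]) -> list[str]:
    """Channel-major layout: CH1:MAV, CH1:WL, ..., CH8:SSC."""
    return [f"{ch}:{feat}" for ch in channel_names for feat in features]


def extract_trials(
    record: SignalRecord,
    mask: ActivityMask,
    config: RunConfig,
    label: int,
    window_length_s: float | None = None,
) -> list[FeatureTrial]:
    """One labelled feature trial per analysis window.

    Features are the config's feature set in canonical order, over the
    config's channel subset (all channels if unset), concatenated
    channel-major.  With 7 features and 8 channels each trial holds 56
    values.  ``window_length_s`` defaults to the first configured length.
    """
    features = config.ordered_features()
    channels = config.channel_subset
    if channels is None:
        channels = list(range(record.n_channels))
    for ch in channels:
        if not 0 <= ch < record.n_channels:
            raise ParameterError(
                f"channel index {ch} out of range for {record.n_channels} channels"
            )
    if window_length_s is None:
        window_length_s = config.window_lengths_s[0]
    names = trial_feature_names(
        features, [record.channel_names[ch] for ch in channels]
    )
    funcs = [FEATURE_FUNCTIONS[f] for f in features]
    trials = []
    for win in segment_windows(record, mask, window_length_s, config.overlap_fraction):
        values = np.array(
            [fn(win.channel(ch)) for ch in channels for fn in funcs]
        )
        trials.append(
            FeatureTrial(
                values=values,
                label=label,
                feature_names=names,
                provenance={
                    "subject": record.meta.get("subject"),
                    "session": record.meta.get("session"),
                    "movement": record.meta.get("movement"),
                    "start_sample": win.start_sample,
                    "window_length_s": window_length_s,
                },
            )
        )
    return trials
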