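"""Preprocessing chain: line-noise notch, wavelet baseline removal,
wavelet envelope, and logic-signal activity detection.

All IIR stages run forward-backward (zero phase) so burst onsets are not
shifted — the analysis is offline and phase linearity matters more than
causality here.  Wavelet transforms use symmetric boundary padding and
reconstructions are truncated to the input length.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import signal

from .errors import LengthError, ParameterError
from .records import ActivityMask, EnvelopeSignal, SignalRecord, segments_from_bool

logger = logging.getLogger(__name__)

NOTCH_BAND_HZ = (59.0, 61.0)
NOTCH_ORDER = 2
BASELINE_WAVELET = "db4"
BASELINE_LEVEL = 8
ENVELOPE_WAVELET = "haar"
ENVELOPE_LEVEL = 8


def notch_line(record: SignalRecord) -> SignalRecord:
    """Suppress 60 Hz line interference.

    Order-2 Butterworth band-stop, 59–61 Hz, applied forward-backward on
    every channel.  Requires the stop band to sit below Nyquist
    (fs > 122 Hz).
    """
    if record.fs <= 2 * NOTCH_BAND_HZ[1]:
        raise ParameterError(
            f"sampling rate {record.fs} Hz too low for a {NOTCH_BAND_HZ} Hz notch"
        )
    sos = signal.butter(
        NOTCH_ORDER, NOTCH_BAND_HZ, btype="bandstop", fs=record.fs, output="sos"
    )
    out = signal.sosfiltfilt(sos, record.data, axis=1)
    return record.copy_with(out)


def _approximation(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Reconstruct only the level-``level`` approximation of a 1-D signal."""
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return rec[: len(x)]


def _check_length(record: SignalRecord, level: int) -> None:
    if record.n_samples < 2**level:
        raise LengthError(
            f"record of {record.n_samples} samples shorter than one "
            f"level-{level} support ({2**level} samples)"
        )


def remove_baseline_dwt(record: SignalRecord) -> SignalRecord:
    """Remove baseline wander by deep-approximation subtraction.

    Each channel is decomposed to 8 levels with Daubechies-4; the level-8
    approximation (the sub-0.5 Hz content at 250 Hz) is reconstructed and
    subtracted, leaving the sEMG band untouched.
    """
    _check_length(record, BASELINE_LEVEL)
    out = np.empty_like(record.data)
    for ch in range(record.n_channels):
        approx = _approximation(record.data[ch], BASELINE_WAVELET, BASELINE_LEVEL)
        out[ch] = record.data[ch] - approx
    return record.copy_with(out)


def compute_envelope(record: SignalRecord) -> EnvelopeSignal:
    """Amplitude envelope from the rectified signal's Haar approximation.

    Each channel is rectified, decomposed to 8 levels with the Haar
    wavelet, and the approximation reconstructed; the mean across channels
    is the combined envelope used for activity detection.  Rectification
    is required: the deep approximation of a zero-mean signal is ~0.
    Small negative reconstruction excursions are clipped to zero.
    """
    _check_length(record, ENVELOPE_LEVEL)
    per_channel = np.empty_like(record.data)
    for ch in range(record.n_channels):
        approx = _approximation(
            np.abs(record.data[ch]), ENVELOPE_WAVELET, ENVELOPE_LEVEL
        )
        per_channel[ch] = np.clip(approx, 0.0, None)
    combined = per_channel.mean(axis=0)
    return EnvelopeSignal(values=combined, fs=record.fs, per_channel=per_channel)


def detect_activity(
    env: EnvelopeSignal,
    rest_reference: tuple[int, int],
    k_hi: float = 3.0,
    k_lo: float = 1.0,
    min_duration_s: float = 0.2,
    min_gap_s: float = 0.2,
) -> ActivityMask:
    """Convert the envelope to a logic signal by hysteresis thresholding.

    Rest statistics (mean, sd) come from the known-rest sample interval
    ``rest_reference`` (the protocol starts with a rest period).  A sample
    turns the mask on when the envelope exceeds ``mu + k_hi * sd`` and the
    mask stays on until the envelope falls below ``mu + k_lo * sd``.
    Gaps shorter than ``min_gap_s`` are merged, then segments shorter
    than ``min_duration_s`` are dropped.
    """
    start, stop = rest_reference
    n = env.n_samples
    if not (0 <= start < stop <= n):
        raise ParameterError(
            f"rest interval [{start}, {stop}) outside record of {n} samples"
        )
    rest = env.values[start:stop]
    mu = float(np.mean(rest))
    sd = float(np.std(rest))
    hi = mu + k_hi * sd
    lo = mu + k_lo * sd

    active = _hysteresis(env.values, hi, lo)
    active = _merge_short_gaps(active, round(min_gap_s * env.fs))
    active = _drop_short_segments(active, round(min_duration_s * env.fs))
    mask = ActivityMask(active=active, fs=env.fs)
    logger.info(
        "detect_activity: thresholds hi=%.4g lo=%.4g mV, %d segments, %.1f%% active",
        hi,
        lo,
        len(mask.segments),
        100.0 * mask.n_active / max(n, 1),
    )
    return mask


def _hysteresis(x: np.ndarray, hi: float, lo: float) -> np.ndarray:
    """Schmitt-trigger thresholding; only threshold crossings can flip state."""
    active = np.zeros(len(x), dtype=bool)
    state = False
    prev = 0
    for i in np.flatnonzero((x > hi) | (x < lo)):
        active[prev:i] = state
        state = x[i] > hi if not state else not (x[i] < lo)
        prev = i
    active[prev:] = state
    return active


def _merge_short_gaps(active: np.ndarray, min_gap: int) -> np.ndarray:
    if min_gap <= 0:
        return active
    out = active.copy()
    segs = segments_from_bool(active)
    for (_, stop_a), (start_b, _) in zip(segs[:-1], segs[1:]):
        if start_b - stop_a < min_gap:
            out[stop_a:start_b] = True
    return out


def _drop_short_segments(active: np.ndarray, min_len: int) -> np.ndarray:
    if min_len <= 0:
        return active
    out = active.copy()
    for start, stop in segments_from_bool(active):
        if stop - start < min_len:
            out[start:stop] = False
    return out


def preprocess_record(
    record: SignalRecord,
    rest_reference_s: tuple[float, float] | None = None,
    **detect_kwargs,
) -> tuple[SignalRecord, EnvelopeSignal, ActivityMask]:
    """Full chain: notch -> baseline removal -> envelope -> activity mask.

    ``rest_reference_s`` defaults to the interval stored in the record's
    metadata (``meta["rest_reference_s"]``) or, failing that, the first
    10 s of the recording.
    """
    clean = remove_baseline_dwt(notch_line(record))
    env = compute_envelope(clean)
    if rest_reference_s is None:
        rest_reference_s = record.meta.get("rest_reference_s", (0.0, 10.0))
    rest = (
        round(rest_reference_s[0] * record.fs),
        round(rest_reference_s[1] * record.fs),
    )
    mask = detect_activity(env, rest, **detect_kwargs)
    return clean, env, mask
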