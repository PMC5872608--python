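"""Separation of volitional/evoked sEMG from FES stimulus contamination.

The stimulus artifact of a constant-frequency pulse train concentrates its
energy at the stimulation frequency and its harmonics, so a comb of
narrow band-stop filters removes it while conserving every sample — no
blanking, which matters for downstream control applications.  Condition
comparison reports RMS and MAV over the active samples of the evoked-only
and volitional+evoked blocks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ParameterError
from .features import mav, rms
from .records import ActivityMask, SignalRecord

logger = logging.getLogger(__name__)

SUPPORTED_STIM_FREQS = (30.0, 50.0)
STOP_HALF_WIDTH_HZ = 1.0
COMB_ORDER = 2


def comb_stop_bands(
    stim_freq: float, fs: float, harmonics: bool = True
) -> list[tuple[float, float]]:
    """±1 Hz stop bands at the stimulation frequency (and its in-band harmonics)."""
    if stim_freq not in SUPPORTED_STIM_FREQS:
        raise ParameterError(
            f"stimulation frequency must be one of {SUPPORTED_STIM_FREQS}, "
            f"got {stim_freq}"
        )
    centers = [stim_freq]
    if harmonics:
        k = 2
        while k * stim_freq < fs / 2:
            centers.append(k * stim_freq)
            k += 1
    return [(c - STOP_HALF_WIDTH_HZ, c + STOP_HALF_WIDTH_HZ) for c in centers]


def remove_stimulus_artifact(
    record: SignalRecord, stim_freq: float, harmonics: bool = True
) -> SignalRecord:
    """Comb-filter the stimulus artifact out of a recording.

    A cascade of order-2 Butterworth band-stops (±1 Hz) centred on the
    stimulation frequency and, when ``harmonics`` is on, every harmonic
    below Nyquist (30 Hz → 30/60/90/120; 50 Hz → 50/100 at 250 Hz), each
    applied forward-backward.  The sample count is conserved and no
    interval is blanked.
    """
    out = record.data
    for band in comb_stop_bands(stim_freq, record.fs, harmonics):
        sos = signal.butter(COMB_ORDER, band, btype="bandstop", fs=record.fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=1)
    logger.info(
        "comb filter at %g Hz (%s harmonics): %d stop bands",
        stim_freq,
        "with" if harmonics else "no",
        len(comb_stop_bands(stim_freq, record.fs, harmonics)),
    )
    return record.copy_with(out)


def compare_conditions(
    evoked_block: SignalRecord,
    combined_block: SignalRecord,
    mask: ActivityMask,
) -> pd.DataFrame:
    """Per-channel RMS and MAV over active samples of the two conditions.

    Both blocks must already be artifact-filtered and share the window
    definition given by ``mask`` (one mask, applied to both).  Returns a
    table with one row per channel and columns
    ``rms_evoked_mv, mav_evoked_mv, rms_combined_mv, mav_combined_mv``.
    """
    if mask.n_active == 0:
        raise ParameterError("activity mask selects no samples")
    rows = []
    for name, block in (("evoked", evoked_block), ("combined", combined_block)):
        if block.n_samples != len(mask.active):
            raise ParameterError(f"mask length does not match the {name} block")
    active = mask.active
    for ch, ch_name in enumerate(evoked_block.channel_names):
        e = evoked_block.data[ch, active]
        c = combined_block.data[ch, active]
        rows.append(
            {
                "channel": ch_name,
                "rms_evoked_mv": rms(e),
                "mav_evoked_mv": mav(e),
                "rms_combined_mv": rms(c),
                "mav_combined_mv": mav(c),
            }
        )
    return pd.DataFrame(rows)


def spectrogram_qc(
    record: SignalRecord,
    channel: int = 0,
    window_s: float = 0.5,
    overlap: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude of one channel for visual QC.

    Hann windows of ``window_s`` seconds with 75% overlap; only slices
    fully inside the record are kept, and magnitudes are unscaled DFT
    moduli (so frame-wise Parseval bookkeeping holds exactly).

    Returns ``(freqs_hz, times_s, magnitude)`` with ``magnitude`` of shape
    ``(n_freqs, n_times)``.
    """
    nperseg = round(window_s * record.fs)
    if record.n_samples < nperseg:
        raise ParameterError(
            f"record of {record.n_samples} samples shorter than one "
            f"{nperseg}-sample spectrogram window"
        )
    if not 0 <= channel < record.n_channels:
        raise ParameterError(f"channel {channel} out of range")
    hop = max(1, round(nperseg * (1.0 - overlap)))
    win = signal.windows.hann(nperseg, sym=False)
    x = record.data[channel]
    starts = np.arange(0, record.n_samples - nperseg + 1, hop)
    frames = np.stack([x[s : s + nperseg] * win for s in starts])
    spectra = np.abs(np.fft.rfft(frames, axis=1)).T
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / record.fs)
    times = (starts + nperseg / 2) / record.fs
    return freqs, times, spectra


def save_spectrogram_png(
    record: SignalRecord, path, channel: int = 0, title: str | None = None
):
    """Write a spectrogram QC figure (log-magnitude, dB) for one channel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    freqs, times, mag = spectrogram_qc(record, channel=channel)
    fig, ax = plt.subplots(figsize=(8, 4))
    db = 20 * np.log10(np.maximum(mag, 1e-12))
    pcm = ax.pcolormesh(times, freqs, db, shading="nearest", cmap="magma")
    fig.colorbar(pcm, ax=ax, label="magnitude (dB)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title or f"{record.channel_names[channel]} spectrogram")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def extract_volitional(
    record: SignalRecord,
    stim_freq: float,
    harmonics: bool = True,
) -> SignalRecord:
    """Full separation chain on an FES trial: baseline removal then comb filter.

    Convenience wrapper for the common case; block-wise analysis slices
    the result using ``record.meta['blocks']`` boundaries.
    """
    from .preprocess import remove_baseline_dwt

    clean = remove_baseline_dwt(record)
    return remove_stimulus_artifact(clean, stim_freq, harmonics)
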