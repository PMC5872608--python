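"""CSV reading/writing for multichannel sEMG recordings.

Dialect: comma-separated, dot decimal, header row ``Time,CH1,...,CH8``
(the time column is matched case-insensitively; any other columns are
channels, kept in header order).  Amplitudes are millivolts throughout.
Values are written at full float precision so that a write/read cycle is
the identity up to float round-off.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .records import SignalRecord

logger = logging.getLogger(__name__)

_TIME_ALIASES = {"time", "time (s)", "time_s", "t"}


def read_recording_csv(path: str | Path, fs_hint: float | None = None) -> SignalRecord:
    """Load a recording CSV into a :class:`SignalRecord`.

    The sampling rate is inferred from the median time step unless
    ``fs_hint`` is given; a hint disagreeing with the inferred rate by
    more than 1% raises :class:`FormatError`.

    Raises
    ------
    FormatError
        Missing or non-monotone time column, ragged rows (the pandas
        parser error names the offending line), or fs mismatch.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows: message carries the line
        raise FormatError(f"{path}: malformed CSV: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus at least one channel")

    time_col = None
    for col in df.columns:
        if str(col).strip().lower() in _TIME_ALIASES:
            time_col = col
            break
    if time_col is None:
        raise FormatError(
            f"{path}: no time column found (header columns: {list(df.columns)})"
        )

    time = df[time_col].to_numpy(dtype=float)
    if len(time) >= 2:
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise FormatError(f"{path}: time column is not strictly increasing")
        fs = 1.0 / float(np.median(steps))
    elif fs_hint is not None:
        fs = float(fs_hint)
    else:
        raise FormatError(f"{path}: cannot infer sampling rate from <2 samples")

    if fs_hint is not None and len(time) >= 2:
        if abs(fs - fs_hint) > 0.01 * fs_hint:
            raise FormatError(
                f"{path}: inferred fs {fs:.4g} Hz disagrees with hint "
                f"{fs_hint:.4g} Hz by more than 1%"
            )
        fs = float(fs_hint)

    channel_names = [str(c) for c in df.columns if c != time_col]
    data = df[[c for c in df.columns if c != time_col]].to_numpy(dtype=float).T
    logger.info(
        "read %s: %d channels x %d samples at %.6g Hz", path, *data.shape, fs
    )
    return SignalRecord(data=data, fs=fs, time=time, channel_names=channel_names)


def write_recording_csv(record: SignalRecord, path: str | Path) -> Path:
    """Write a record as ``Time,<channels...>`` CSV, one row per sample."""
    record.validate()
    path = Path(path)
    df = pd.DataFrame({"Time": record.time})
    for name, row in zip(record.channel_names, record.data):
        df[name] = row
    try:
        # pandas emits repr-precision floats by default: lossless round-trip
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write recording to {path}: {exc}") from exc
    logger.info(
        "wrote %s: %d channels x %d samples", path, record.n_channels, record.n_samples
    )
    return path


def write_ground_truth_csv(truth, fs: float, path: str | Path) -> Path:
    """Sidecar CSV for a synthetic record's ground truth.

    Columns: Time, mask, then per-channel volitional/artifact/evoked
    components (same dialect as the recording itself).
    """
    path = Path(path)
    n = len(truth.activity_mask)
    df = pd.DataFrame({"Time": np.arange(n) / fs, "mask": truth.activity_mask.astype(int)})
    for comp_name in ("volitional_component", "artifact_component", "evoked_component"):
        comp = getattr(truth, comp_name)
        for ch in range(comp.shape[0]):
            df[f"{comp_name.split('_')[0]}_CH{ch + 1}"] = comp[ch]
    df.to_csv(path, index=False)
    return path


def write_trials_csv(trials, path: str | Path) -> Path:
    """Trials table: label, window metadata, then one column per feature."""
    if not trials:
        raise ParameterError("no trials to write")
    rows = []
    for t in trials:
        row = {"label": t.label}
        row.update({f"prov_{k}": v for k, v in t.provenance.items()})
        row.update(dict(zip(t.feature_names, t.values)))
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
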