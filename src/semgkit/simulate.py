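"""Synthetic multichannel sEMG generator with stage-wise ground truth.

The generator emulates the recording protocol the analysis chain targets:
8-channel recordings at 250 Hz of alternating rest / isometric-contraction
blocks, contaminated with slow baseline drift, 60 Hz line interference and
wideband sensor noise, plus — for stimulation trials — a periodic biphasic
stimulus-artifact pulse train with an M-wave-like evoked response after
each pulse.

Volitional sEMG is modelled as amplitude-modulated band-limited Gaussian
noise (20–95 Hz, respecting the 125 Hz Nyquist limit), the standard
surrogate when no motor-unit-level simulation is wanted.  Every additive
component is logged in a :class:`GroundTruth` so each downstream stage can
be validated against what was actually injected:
``data = volitional + artifact + evoked + drift + line + noise`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import signal

from .errors import DegenerateProfileError, ParameterError
from .records import DEFAULT_FS, N_CHANNELS, SignalRecord

#: sEMG band of the volitional surrogate (Hz); upper edge below Nyquist at 250 Hz.
SEMG_BAND_HZ = (20.0, 95.0)

#: Length of the raised-cosine activation edges (s).
DEFAULT_EDGE_S = 0.1

#: Per-channel active-contraction RMS (mV).  Channels 1-3 and 7 carry the
#: movement-discriminative differences; the remaining channels respond
#: identically for both movements.
DEFAULT_GAINS = {
    "hand_open": (0.80, 0.25, 0.70, 0.35, 0.30, 0.30, 0.20, 0.30),
    "power_grasp": (0.25, 0.75, 0.20, 0.35, 0.30, 0.30, 0.80, 0.30),
}

MOVEMENT_LABELS = {
    "hand_open": 1,
    "power_grasp": 2,
    "fine_pinch": 3,
    "pronation": 4,
    "supination": 5,
}


@dataclass(frozen=True)
class MovementProfile:
    """A movement's per-channel activation strengths.

    ``channel_gains`` are the active-phase RMS amplitudes (mV) of the
    volitional sEMG on each channel.  Labels 1 and 2 are reserved for hand
    open and power grasp respectively.
    """

    name: str
    label: int
    channel_gains: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.name in MOVEMENT_LABELS and MOVEMENT_LABELS[self.name] != self.label:
            raise ParameterError(
                f"movement {self.name!r} must carry label {MOVEMENT_LABELS[self.name]}"
            )
        if any(g < 0 for g in self.channel_gains):
            raise DegenerateProfileError(
                f"profile {self.name!r} has negative channel gains"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_gains)


def default_profiles() -> dict[str, MovementProfile]:
    """Hand-open / power-grasp profile pair with discriminative CH1-3, CH7."""
    return {
        name: MovementProfile(name=name, label=MOVEMENT_LABELS[name], channel_gains=g)
        for name, g in DEFAULT_GAINS.items()
    }


@dataclass(frozen=True)
class StimulusSpec:
    """FES pulse-train parameters (one row of the stimulation protocol)."""

    pulse_amplitude_ma: float = 10.0
    pulse_width_us: float = 300.0
    pulse_frequency_hz: float = 30.0
    on_time_s: float = 1.0
    off_time_s: float = 3.0

    def __post_init__(self) -> None:
        if self.pulse_frequency_hz not in (30.0, 50.0):
            raise ParameterError(
                f"pulse frequency must be 30 or 50 Hz, got {self.pulse_frequency_hz}"
            )
        if self.on_time_s <= 0 or self.off_time_s <= 0:
            raise ParameterError("on/off times must be positive")

    @property
    def period_s(self) -> float:
        return self.on_time_s + self.off_time_s


@dataclass
class GroundTruth:
    """Everything the generator injected, split by origin.

    All component arrays have the emitted record's shape; they sum with
    ``drift + line + noise`` to the record's data exactly by construction.
    """

    activity_mask: np.ndarray
    volitional_component: np.ndarray
    artifact_component: np.ndarray
    evoked_component: np.ndarray
    drift_component: np.ndarray = field(default=None)  # type: ignore[assignment]
    line_component: np.ndarray = field(default=None)  # type: ignore[assignment]
    noise_component: np.ndarray = field(default=None)  # type: ignore[assignment]


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the sEMG band."""
    sos = signal.butter(4, SEMG_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _raised_cosine_burst(n_burst: int, n_edge: int) -> np.ndarray:
    """Unit plateau with raised-cosine rise/fall occupying the burst ends."""
    burst = np.ones(n_burst)
    n_edge = min(n_edge, n_burst // 2)
    if n_edge > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_edge) / n_edge))
        burst[:n_edge] = ramp
        burst[-n_edge:] = ramp[::-1]
    return burst


def _drift(
    rng: np.random.Generator, n: int, fs: float, amplitude_mv: float
) -> np.ndarray:
    """Slow baseline wander: sum of sub-0.4 Hz sinusoids."""
    t = np.arange(n) / fs
    freqs = (0.05, 0.12, 0.21, 0.33)
    weights = (0.50, 0.25, 0.15, 0.10)
    out = np.zeros(n)
    for f, w in zip(freqs, weights):
        out += amplitude_mv * w * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return out


def _assemble(
    rng: np.random.Generator,
    active_starts_s: Iterable[float],
    burst_s: float,
    total_s: float,
    gains: tuple[float, ...],
    fs: float,
    edge_s: float,
    drift_amplitude_mv: float,
    line_amplitude_mv: float,
    noise_rms_mv: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Common core: volitional bursts + drift + line + noise, with mask."""
    n = round(total_s * fs)
    n_ch = len(gains)
    n_burst = round(burst_s * fs)
    n_edge = round(edge_s * fs)

    envelope = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    burst = _raised_cosine_burst(n_burst, n_edge)
    for start_s in active_starts_s:
        s = round(start_s * fs)
        envelope[s : s + n_burst] = burst
        mask[s : s + n_burst] = True

    volitional = np.zeros((n_ch, n))
    drift = np.zeros((n_ch, n))
    line = np.zeros((n_ch, n))
    noise = np.zeros((n_ch, n))
    t = np.arange(n) / fs
    for ch in range(n_ch):
        if gains[ch] > 0:
            volitional[ch] = gains[ch] * envelope * _bandlimited_noise(rng, n, fs)
        if drift_amplitude_mv > 0:
            drift[ch] = _drift(rng, n, fs, drift_amplitude_mv)
        if line_amplitude_mv > 0:
            line[ch] = line_amplitude_mv * np.sin(
                2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
            )
        noise[ch] = noise_rms_mv * rng.standard_normal(n)
    return mask, envelope, volitional, drift, line, noise


def generate_session(
    profile: MovementProfile,
    n_reps: int = 10,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    contraction_s: float = 10.0,
    rest_s: float = 10.0,
    edge_s: float = DEFAULT_EDGE_S,
    drift_amplitude_mv: float = 0.5,
    line_amplitude_mv: float = 0.05,
    noise_rms_mv: float = 0.01,
    session: int = 1,
    subject: str = "synthetic",
) -> tuple[SignalRecord, GroundTruth]:
    """One recording session: initial rest, then ``n_reps`` contraction/rest cycles.

    The record lasts ``rest_s + n_reps * (contraction_s + rest_s)`` seconds
    (210 s for the default 10-repetition protocol).  The activity mask is
    true exactly during the contraction plateaus.
    """
    if n_reps < 1:
        raise ParameterError(f"n_reps must be at least 1, got {n_reps}")
    starts = [rest_s + k * (contraction_s + rest_s) for k in range(n_reps)]
    total_s = rest_s + n_reps * (contraction_s + rest_s)
    rng = np.random.default_rng(seed)
    mask, _, volitional, drift, line, noise = _assemble(
        rng,
        starts,
        contraction_s,
        total_s,
        profile.channel_gains,
        fs,
        edge_s,
        drift_amplitude_mv,
        line_amplitude_mv,
        noise_rms_mv,
    )
    n_ch = profile.n_channels
    zeros = np.zeros_like(volitional)
    data = volitional + drift + line + noise
    record = SignalRecord(
        data=data,
        fs=fs,
        meta={
            "subject": subject,
            "movement": profile.name,
            "label": profile.label,
            "session": session,
            "kind": "volitional",
            "rest_reference_s": (0.0, rest_s),
        },
    )
    truth = GroundTruth(
        activity_mask=mask,
        volitional_component=volitional,
        artifact_component=zeros,
        evoked_component=zeros.copy(),
        drift_component=drift,
        line_component=line,
        noise_component=noise,
    )
    assert record.n_channels == n_ch
    return record, truth


def _biphasic_harmonics(f0: float, pulse_width_s: float, n_harmonics: int) -> np.ndarray:
    """Fourier coefficients c_h (h=1..H) of a unit biphasic pulse train.

    The pulse is +1 for ``pulse_width_s`` immediately followed by −1 for the
    same width (charge-balanced), repeating with period 1/f0.
    """
    T = 1.0 / f0
    w = pulse_width_s
    h = np.arange(1, n_harmonics + 1)
    om = 2j * np.pi * h / T
    seg = (1.0 - np.exp(-om * w)) / om  # ∫_0^w e^{-om t} dt
    return (seg - np.exp(-om * w) * seg) / T


def _artifact_burst(
    t: np.ndarray, f0: float, pulse_width_s: float, fs: float
) -> np.ndarray:
    """Band-limited periodic stimulus artifact over relative times ``t``.

    A constant-frequency stimulator is strictly periodic, so the sampled
    artifact is the Fourier synthesis of the biphasic train truncated at
    Nyquist: all its energy sits exactly at f0 and its in-band harmonics.
    Returned with unit peak amplitude.
    """
    n_harmonics = int(np.floor((fs / 2) / f0))
    c = _biphasic_harmonics(f0, pulse_width_s, n_harmonics)
    h = np.arange(1, n_harmonics + 1)
    burst = 2.0 * np.real(c @ np.exp(2j * np.pi * f0 * np.outer(h, t)))
    peak = np.max(np.abs(burst))
    return burst / peak if peak > 0 else burst


def _mwave(t: np.ndarray, freq_hz: float, decay_s: float) -> np.ndarray:
    """Damped sinusoid (unit peak) evaluated at continuous times ``t >= 0``."""
    k = np.sin(2 * np.pi * freq_hz * t) * np.exp(-t / decay_s)
    # continuous-time peak of sin(wt)e^{-t/tau} at t* = atan(w*tau)/w
    w = 2 * np.pi * freq_hz
    t_star = np.arctan(w * decay_s) / w
    peak = np.sin(w * t_star) * np.exp(-t_star / decay_s)
    return k / peak


def generate_fes_trial(
    profile: MovementProfile,
    stim: StimulusSpec,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    n_reps_per_block: int = 5,
    edge_s: float = DEFAULT_EDGE_S,
    artifact_amplitude_mv: float = 2.0,
    evoked_amplitude_mv: float = 0.5,
    evoked_freq_hz: float = 90.0,
    evoked_decay_s: float = 0.005,
    evoked_duration_s: float = 0.02,
    drift_amplitude_mv: float = 0.5,
    line_amplitude_mv: float = 0.05,
    noise_rms_mv: float = 0.01,
    subject: str = "synthetic",
) -> tuple[SignalRecord, GroundTruth]:
    """One FES trial: three consecutive 5-repetition blocks.

    Block layout (each repetition = ``on_time_s`` active + ``off_time_s``
    rest):

    a. volitional contractions only,
    b. FES only (stimulus artifact + evoked response, no volitional drive),
    c. volitional contractions during FES.

    The stimulus artifact is a biphasic pulse train at the stimulation
    frequency (harmonic-rich by construction); each pulse is followed by a
    damped-sinusoid evoked response emulating an M-wave.  Block boundaries
    are recorded in ``record.meta["blocks"]`` as half-open sample ranges.
    """
    period = stim.period_s
    block_s = n_reps_per_block * period
    total_s = 3 * block_s
    n = round(total_s * fs)
    n_ch = profile.n_channels

    # active on-periods: (block index, start time)
    on_starts = {
        blk: [blk * block_s + r * period for r in range(n_reps_per_block)]
        for blk in range(3)
    }
    volitional_starts = on_starts[0] + on_starts[2]
    fes_blocks = (1, 2)

    rng = np.random.default_rng(seed)
    mask, _, volitional, drift, line, noise = _assemble(
        rng,
        volitional_starts,
        stim.on_time_s,
        total_s,
        profile.channel_gains,
        fs,
        edge_s,
        drift_amplitude_mv,
        line_amplitude_mv,
        noise_rms_mv,
    )
    # muscle is active (volitionally or via FES) during every on-period
    n_on = round(stim.on_time_s * fs)
    for blk in range(3):
        for start_s in on_starts[blk]:
            s = round(start_s * fs)
            mask[s : s + n_on] = True

    artifact = np.zeros((n_ch, n))
    evoked = np.zeros((n_ch, n))
    f0 = stim.pulse_frequency_hz
    n_pulses = int(np.floor(stim.on_time_s * f0))
    n_kernel = round(evoked_duration_s * fs)
    mwave_latency_s = 0.005  # conduction delay between pulse and M-wave onset
    for blk in fes_blocks:
        for start_s in on_starts[blk]:
            s = round(start_s * fs)
            stop = min(s + n_on, n)
            t_rel = np.arange(s, stop) / fs - start_s
            if artifact_amplitude_mv > 0:
                artifact[:, s:stop] += artifact_amplitude_mv * _artifact_burst(
                    t_rel, f0, stim.pulse_width_us * 1e-6, fs
                )
            if evoked_amplitude_mv > 0:
                for k in range(n_pulses):
                    tp = start_s + k / f0 + mwave_latency_s
                    i0 = int(np.ceil(tp * fs))
                    i1 = min(i0 + n_kernel, n)
                    if i0 >= i1:
                        continue
                    tk = np.arange(i0, i1) / fs - tp
                    evoked[:, i0:i1] += evoked_amplitude_mv * _mwave(
                        tk, evoked_freq_hz, evoked_decay_s
                    )

    data = volitional + artifact + evoked + drift + line + noise
    blocks = {
        name: (round(blk * block_s * fs), round((blk + 1) * block_s * fs))
        for blk, name in enumerate(("volitional", "fes", "combined"))
    }
    record = SignalRecord(
        data=data,
        fs=fs,
        meta={
            "subject": subject,
            "movement": profile.name,
            "label": profile.label,
            "kind": "fes_trial",
            "blocks": blocks,
            "stim": {
                "pulse_amplitude_ma": stim.pulse_amplitude_ma,
                "pulse_width_us": stim.pulse_width_us,
                "pulse_frequency_hz": stim.pulse_frequency_hz,
                "on_time_s": stim.on_time_s,
                "off_time_s": stim.off_time_s,
            },
        },
    )
    truth = GroundTruth(
        activity_mask=mask,
        volitional_component=volitional,
        artifact_component=artifact,
        evoked_component=evoked,
        drift_component=drift,
        line_component=line,
        noise_component=noise,
    )
    return record, truth
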