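"""Run configuration: the tunable knobs of the analysis chain.

Defaults reproduce the study protocol this package emulates: seven window
lengths from 20 ms to 3 s at 25% overlap, the seven time-domain features,
a 70/30 split repeated ten times, and a 90% accuracy selection threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ParameterError

#: Canonical feature ordering used everywhere a feature subset is expanded.
CANONICAL_FEATURES = ("MAV", "WL", "ZC", "SD", "IAV", "V", "SSC")

DEFAULT_WINDOW_LENGTHS_S = (0.02, 0.05, 0.10, 0.30, 0.50, 1.0, 3.0)


@dataclass
class RunConfig:
    """Parameters of a windowing / feature / classification run.

    ``channel_subset`` uses 0-based channel indices (``None`` = all
    channels).  ``feature_set`` is any subset of
    ``{MAV, WL, ZC, SD, IAV, V, SSC}``; it is always expanded in canonical
    order regardless of the order given.
    """

    window_lengths_s: list[float] = field(
        default_factory=lambda: list(DEFAULT_WINDOW_LENGTHS_S)
    )
    overlap_fraction: float = 0.25
    feature_set: list[str] = field(default_factory=lambda: list(CANONICAL_FEATURES))
    channel_subset: list[int] | None = None
    train_fraction: float = 0.70
    n_repetitions: int = 10
    accuracy_threshold: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction < 1:
            raise ParameterError(
                f"overlap_fraction must lie in [0, 1), got {self.overlap_fraction}"
            )
        if not 0 < self.train_fraction < 1:
            raise ParameterError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )
        if self.n_repetitions < 1:
            raise ParameterError("n_repetitions must be at least 1")
        unknown = set(self.feature_set) - set(CANONICAL_FEATURES)
        if unknown:
            raise ParameterError(f"unknown features: {sorted(unknown)}")
        # keep canonical ordering, drop duplicates
        self.feature_set = [f for f in CANONICAL_FEATURES if f in set(self.feature_set)]
        if not self.feature_set:
            raise ParameterError("feature_set must not be empty")

    def ordered_features(self) -> list[str]:
        return list(self.feature_set)


def load_config(path: str | Path) -> RunConfig:
    """Read a :class:`RunConfig` from a YAML file (missing keys = defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParameterError(f"config file {path} must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    return path
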