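"""End-to-end convenience flows built from the stage modules.

These wire together generation (or loaded recordings), preprocessing,
feature extraction and classification the way the acquisition protocol
is analysed: one session per movement to train, a second to test.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .classify import TrialSet, assemble_trials, cross_session_evaluate, SelectionResult
from .config import RunConfig
from .features import extract_trials
from .preprocess import preprocess_record
from .records import FeatureTrial, SignalRecord
from .simulate import MovementProfile, default_profiles, generate_session

logger = logging.getLogger(__name__)


def record_to_trials(
    record: SignalRecord,
    config: RunConfig,
    label: int,
    window_length_s: float | None = None,
) -> list[FeatureTrial]:
    """Preprocess one recording and extract its labelled feature trials."""
    clean, _, mask = preprocess_record(record)
    return extract_trials(clean, mask, config, label, window_length_s)


def session_trial_set(
    records_by_movement: Mapping[int, SignalRecord],
    config: RunConfig,
    window_length_s: float | None = None,
) -> TrialSet:
    """Trials of one session (one record per movement label), pooled and shuffled."""
    per_movement = [
        record_to_trials(rec, config, label, window_length_s)
        for label, rec in records_by_movement.items()
    ]
    return assemble_trials(per_movement, config.seed)


def cross_session_accuracy(
    session1: Mapping[int, SignalRecord],
    session2: Mapping[int, SignalRecord],
    config: RunConfig,
    window_length_s: float | None = None,
    chosen: SelectionResult | None = None,
) -> float:
    """Train on session 1, test on session 2; return the accuracy fraction.

    With ``chosen`` given, only that configuration's channel/feature
    columns are used; otherwise the config's own channel subset and
    feature set define the columns directly.
    """
    ts1 = session_trial_set(session1, config, window_length_s)
    ts2 = session_trial_set(session2, config, window_length_s)
    if chosen is not None:
        return cross_session_evaluate(ts1, ts2, chosen)
    from .classify import evaluate, train_lda

    model = train_lda(ts1)
    acc = evaluate(model, ts2)
    logger.info(
        "cross-session accuracy %.2f%% (%d train / %d test trials)",
        100 * acc,
        ts1.n_trials,
        ts2.n_trials,
    )
    return acc


def synthetic_two_session_experiment(
    config: RunConfig,
    seed: int,
    profiles: Sequence[MovementProfile] | None = None,
    n_reps: int = 10,
) -> tuple[dict[int, SignalRecord], dict[int, SignalRecord]]:
    """Generate the two-session / two-movement recording layout.

    Session ``s`` of movement ``m`` uses seed
    ``seed + 101 * label + session_index`` so every record draws an
    independent stream while remaining reproducible from one master seed.
    """
    if profiles is None:
        profiles = list(default_profiles().values())
    sessions: list[dict[int, SignalRecord]] = []
    for s in (1, 2):
        records = {}
        for prof in profiles:
            rec, _ = generate_session(
                prof,
                n_reps=n_reps,
                seed=seed + 101 * prof.label + s,
                session=s,
            )
            records[prof.label] = rec
        sessions.append(records)
    return sessions[0], sessions[1]
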