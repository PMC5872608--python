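"""Two-class linear discriminant analysis and the window/channel/feature
selection procedure built on it.

The evaluation mirrors the protocol the feature pipeline feeds: trials of
both movements are pooled and shuffled, split 70/30 stratified by label,
an LDA (class means + pooled within-class covariance with light trace
shrinkage) is trained, and accuracy is the fraction of correctly labelled
test trials.  The split/train/evaluate cycle repeats ``n_repetitions``
times with seeds derived from the master seed, and candidate
channel/feature subsets whose mean accuracy clears the threshold are
retained.  A final model trained on all session-1 trials is evaluated on
untouched session-2 trials for the cross-session figure.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .config import RunConfig
from .errors import ParameterError
from .records import FeatureTrial, as_trial_matrix

logger = logging.getLogger(__name__)


@dataclass
class TrialSet:
    """Aligned trial matrix ``(n_trials, n_features)`` and label vector."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.y):
            raise ParameterError("trial matrix and labels disagree in length")
        if self.X.shape[1] != len(self.feature_names):
            raise ParameterError("trial matrix and feature names disagree in width")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    def select_columns(self, names: Sequence[str]) -> "TrialSet":
        index = {name: i for i, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise ParameterError(f"unknown feature columns: {missing}")
        cols = [index[n] for n in names]
        return TrialSet(self.X[:, cols], self.y.copy(), list(names), self.seed)

    def subset_rows(self, idx: np.ndarray) -> "TrialSet":
        return TrialSet(self.X[idx], self.y[idx], list(self.feature_names), self.seed)


@dataclass
class LDAModel:
    """Two-class linear discriminant with a shared (pooled) covariance.

    ``decision(x) = sign(w·x + b)`` selects ``classes[1]`` for positive
    values; it equals the comparison of the two Gaussian discriminant
    functions by construction.
    """

    classes: np.ndarray
    means: np.ndarray  # (2, p)
    pooled_covariance: np.ndarray  # (p, p), after shrinkage
    priors: np.ndarray  # (2,)
    w: np.ndarray
    b: float
    _solved_means: np.ndarray = field(repr=False, default=None)  # type: ignore

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w + self.b

    def discriminant_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores delta_k(x) = x'S⁻¹mu_k − ½mu_k'S⁻¹mu_k + log pi_k."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a = self._solved_means  # (2, p), rows S⁻¹ mu_k
        const = -0.5 * np.einsum("kp,kp->k", self.means, a) + np.log(self.priors)
        return X @ a.T + const

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) > 0, self.classes[1], self.classes[0])


def assemble_trials(
    trials_per_movement: Sequence[Sequence[FeatureTrial]], seed: int
) -> TrialSet:
    """Pool each movement's trials and shuffle rows with the given seed."""
    labels_seen: set[int] = set()
    pooled: list[FeatureTrial] = []
    for movement_trials in trials_per_movement:
        if not movement_trials:
            raise ParameterError("every movement must contribute at least one trial")
        labels = {t.label for t in movement_trials}
        if len(labels) != 1:
            raise ParameterError(f"mixed labels within one movement: {sorted(labels)}")
        (label,) = labels
        if label in labels_seen:
            raise ParameterError(f"label {label} used by two movements")
        labels_seen.add(label)
        pooled.extend(movement_trials)
    X, y = as_trial_matrix(pooled)
    perm = np.random.default_rng(seed).permutation(len(y))
    return TrialSet(X[perm], y[perm], pooled[0].feature_names, seed=seed)


def split_trials(
    ts: TrialSet, train_fraction: float, seed: int
) -> tuple[TrialSet, TrialSet]:
    """Stratified split: round(train_fraction · n) training trials per class."""
    if not 0 < train_fraction < 1:
        raise ParameterError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in np.unique(ts.y):
        idx = np.flatnonzero(ts.y == label)
        if len(idx) < 2:
            raise ParameterError(
                f"class {label} has {len(idx)} trial(s); need at least 2 to stratify"
            )
        idx = rng.permutation(idx)
        n_train = round(train_fraction * len(idx))
        n_train = min(max(n_train, 1), len(idx) - 1)  # keep both sides nonempty
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return ts.subset_rows(np.sort(train_idx)), ts.subset_rows(np.sort(test_idx))


def train_lda(train: TrialSet, shrinkage: float = 1e-3) -> LDAModel:
    """Fit the two-class LDA.

    Pooled covariance ``S = [(n1−1)S1 + (n2−1)S2] / (n−2)`` is regularized
    as ``(1−γ)S + γ·tr(S)/p·I`` (default γ=1e−3) so small trial counts
    cannot make it singular.
    """
    classes = np.unique(train.y)
    if len(classes) != 2:
        raise ParameterError(f"LDA requires exactly 2 classes, got {len(classes)}")
    p = train.X.shape[1]
    n_total = train.n_trials
    means = np.empty((2, p))
    scatter = np.zeros((p, p))
    counts = np.empty(2)
    for k, label in enumerate(classes):
        Xk = train.X[train.y == label]
        if len(Xk) < 2:
            raise ParameterError(f"class {label} needs at least 2 training trials")
        counts[k] = len(Xk)
        means[k] = Xk.mean(axis=0)
        centered = Xk - means[k]
        scatter += centered.T @ centered
    S = scatter / (n_total - 2)
    S = (1.0 - shrinkage) * S + shrinkage * (np.trace(S) / p) * np.eye(p)
    priors = counts / n_total

    solved = linalg.solve(S, means.T, assume_a="pos").T  # rows S⁻¹ mu_k
    w = solved[1] - solved[0]
    b = float(
        -0.5 * (means[1] @ solved[1] - means[0] @ solved[0])
        + np.log(priors[1] / priors[0])
    )
    return LDAModel(
        classes=classes,
        means=means,
        pooled_covariance=S,
        priors=priors,
        w=w,
        b=b,
        _solved_means=solved,
    )


def evaluate(model: LDAModel, test: TrialSet) -> float:
    """Fraction of correctly classified test trials."""
    if test.n_trials == 0:
        raise ParameterError("cannot evaluate on an empty test set")
    return float(np.mean(model.predict(test.X) == test.y))


@dataclass
class SelectionResult:
    """One scored (window, channels, features) candidate."""

    window_length_s: float
    channel_subset: tuple[str, ...]
    feature_subset: tuple[str, ...]
    mean_accuracy: float
    per_repetition: list[float]


def _column_names(channels: Sequence[str], features: Sequence[str]) -> list[str]:
    return [f"{ch}:{feat}" for ch in channels for feat in features]


def _channel_names_of(ts: TrialSet) -> list[str]:
    seen: list[str] = []
    for name in ts.feature_names:
        ch = name.split(":", 1)[0]
        if ch not in seen:
            seen.append(ch)
    return seen


def repeated_split_accuracy(
    ts: TrialSet, config: RunConfig, columns: Sequence[str] | None = None
) -> list[float]:
    """Accuracies of ``n_repetitions`` split/train/evaluate cycles.

    Repetition i uses seed ``config.seed + i`` for its stratified split.
    """
    sub = ts if columns is None else ts.select_columns(columns)
    accs = []
    for rep in range(config.n_repetitions):
        train, test = split_trials(sub, config.train_fraction, config.seed + rep)
        accs.append(evaluate(train_lda(train), test))
    return accs


def select_configuration(
    session1: Mapping[float, Sequence[Sequence[FeatureTrial]]],
    config: RunConfig,
    max_feature_subset_size: int | None = None,
) -> list[SelectionResult]:
    """Score candidate subsets per window length; keep those above threshold.

    ``session1`` maps window length (s) to the per-movement trial lists of
    the first session.  The search is exhaustive over feature subsets
    (optionally capped in size) crossed with greedy-forward channel
    selection; every greedy step's chosen subset is scored over
    ``n_repetitions`` repeated splits.  Results with mean accuracy above
    ``config.accuracy_threshold`` are returned sorted by mean accuracy
    (descending), ties broken by fewer channels, fewer features, shorter
    window.
    """
    features = config.ordered_features()
    max_size = max_feature_subset_size or len(features)
    results: list[SelectionResult] = []
    for window_length_s, per_movement in session1.items():
        ts = assemble_trials(per_movement, config.seed)
        channels = _channel_names_of(ts)
        for size in range(1, max_size + 1):
            for feat_subset in itertools.combinations(features, size):
                results.extend(
                    _greedy_channels(ts, channels, feat_subset, config, window_length_s)
                )
    retained = [r for r in results if r.mean_accuracy > config.accuracy_threshold]
    retained.sort(
        key=lambda r: (
            -r.mean_accuracy,
            len(r.channel_subset),
            len(r.feature_subset),
            r.window_length_s,
        )
    )
    if not retained:
        logger.warning(
            "no configuration exceeded the %.0f%% accuracy threshold",
            100 * config.accuracy_threshold,
        )
    return retained


def _greedy_channels(
    ts: TrialSet,
    channels: Sequence[str],
    feat_subset: tuple[str, ...],
    config: RunConfig,
    window_length_s: float,
) -> list[SelectionResult]:
    """Greedy-forward channel growth for one feature subset.

    At each step the channel that best improves mean accuracy joins the
    subset; growth stops when no candidate improves on the current mean.
    The chosen subset of every size is returned as a scored candidate.
    """
    chosen: list[str] = []
    remaining = list(channels)
    best_so_far = -np.inf
    out: list[SelectionResult] = []
    while remaining:
        step_best: tuple[float, str, list[float]] | None = None
        for ch in remaining:
            cols = _column_names(sorted(chosen + [ch], key=channels.index), feat_subset)
            accs = repeated_split_accuracy(ts, config, cols)
            mean = float(np.mean(accs))
            if step_best is None or mean > step_best[0]:
                step_best = (mean, ch, accs)
        mean, ch, accs = step_best
        if mean <= best_so_far:
            break
        best_so_far = mean
        chosen.append(ch)
        chosen.sort(key=channels.index)
        out.append(
            SelectionResult(
                window_length_s=window_length_s,
                channel_subset=tuple(chosen),
                feature_subset=feat_subset,
                mean_accuracy=mean,
                per_repetition=accs,
            )
        )
        remaining.remove(ch)
    return out


def cross_session_evaluate(
    session1: TrialSet, session2: TrialSet, chosen: SelectionResult
) -> float:
    """Train on all session-1 trials of the chosen configuration, test on
    all session-2 trials.  No shuffling crosses the session boundary."""
    cols = _column_names(chosen.channel_subset, chosen.feature_subset)
    model = train_lda(session1.select_columns(cols))
    return evaluate(model, session2.select_columns(cols))
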