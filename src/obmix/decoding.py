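"""Time-resolved linear-SVM decoding of target presence.

The decoder is a max-margin linear classifier with the intercept constrained
to zero (decision = sign of w·amplitudes) and an L2 (ridge-type) penalty of
fixed default strength.  Two designs are analysed:

* *random 80/20 splits*: train on a random 80% of all trials (single odours
  and mixtures), test on the held-out 20%;
* *cross-generalization*: train only on single-odour trials (target vs the
  other singles), test only on mixture trials labelled by target presence —
  asking whether mixture patterns resemble their target component.

Accuracies are balanced (mean of per-class correct rates), so chance is 0.5
whatever the class composition of a session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from .exceptions import (
    InsufficientReplicatesError,
    InvalidArgumentError,
    InvalidDesignError,
    InvalidTrainingSetError,
)
from .transients import ResponseMatrix

__all__ = [
    "DecodingResult",
    "train_linear_decoder",
    "random_split_accuracy",
    "cross_generalization_accuracy",
    "accuracy_significance",
    "ranksum_z_timecourse",
]

log = logging.getLogger(__name__)


@dataclass
class DecodingResult:
    """Accuracy over random splits and time points for one field and design."""

    time_points: np.ndarray  # seconds, window centres
    accuracy: np.ndarray  # n_splits x n_time, balanced accuracies in [0, 1]
    split_spec: str  # "random_80_20" | "train_single_test_mixture"
    n_splits: int
    seed: int
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise InvalidArgumentError("accuracies must lie in [0, 1]")

    def mean_timecourse(self) -> np.ndarray:
        """Split-averaged accuracy per time point."""
        return self.accuracy.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.accuracy.shape[0]):
            for k, t in enumerate(self.time_points):
                rows.append(
                    {
                        "time": float(t),
                        "split": s,
                        "accuracy": self.accuracy[s, k],
                        "design": self.split_spec,
                        "fov_id": self.fov_id,
                    }
                )
        return pd.DataFrame(rows)


class _ZeroInterceptSVM:
    """Thin wrapper around LinearSVC with the intercept fixed at 0."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self._clf = LinearSVC(
            C=C, fit_intercept=False, loss="squared_hinge", random_state=seed,
            max_iter=5000,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ZeroInterceptSVM":
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # liblinear legitimately fails to converge on information-free
            # (pre-onset / shuffled) features; predictions are still defined
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._clf.fit(X, y)
        return self

    @property
    def weights(self) -> np.ndarray:
        return self._clf.coef_.ravel()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict(np.atleast_2d(X))


def train_linear_decoder(
    rm: ResponseMatrix,
    labels: np.ndarray | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> _ZeroInterceptSVM:
    """Fit the zero-intercept linear SVM on a response matrix.

    ``labels`` defaults to the matrix's target-present flags.  The returned
    decoder exposes ``weights`` (length = ROI count) and ``predict``.
    """
    y = rm.labels["target_present"].to_numpy() if labels is None else np.asarray(labels)
    if np.unique(y).size < 2:
        raise InvalidTrainingSetError("training set contains a single class")
    return _ZeroInterceptSVM(C=C, seed=seed).fit(rm.amplitudes, y)


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of per-class correct rates; chance 0.5 for any composition."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    rates = []
    for cls in (True, False):
        m = y_true == cls
        if m.any():
            rates.append(float(np.mean(y_pred[m] == cls)))
    return float(np.mean(rates))


def _draw_split(
    n: int, y: np.ndarray, test_fraction: float, rng: np.random.Generator,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Random partition; redrawn (logged, capped) if either side is single-class."""
    n_test = max(1, int(round(test_fraction * n)))
    for attempt in range(max_retries):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if np.unique(y[train]).size == 2 and np.unique(y[test]).size == 2:
            if attempt:
                log.info("split accepted after %d redraw(s)", attempt)
            return train, test
    raise InvalidTrainingSetError(
        f"could not draw a two-class split in {max_retries} attempts"
    )


def random_split_accuracy(
    rms_per_time: list[tuple[float, ResponseMatrix]],
    test_fraction: float = 0.2,
    n_splits: int = 50,
    seed: int = 0,
    C: float = 1.0,
    resplit_per_time: bool = False,
) -> DecodingResult:
    """Random 80/20 split decoding accuracy over a time course.

    By default the random partitions are drawn once and reused at every time
    point, so the time course reflects coding dynamics rather than split
    noise; ``resplit_per_time=True`` re-randomises at each window.
    """
    if not 0 < test_fraction < 1:
        raise InvalidArgumentError("test_fraction must be in (0, 1)")
    times = np.array([t for t, _ in rms_per_time])
    rm0 = rms_per_time[0][1]
    y = rm0.labels["target_present"].to_numpy()
    rng = np.random.default_rng(seed)
    fixed = (
        None
        if resplit_per_time
        else [_draw_split(rm0.n_trials, y, test_fraction, rng) for _ in range(n_splits)]
    )
    acc = np.empty((n_splits, len(times)))
    for k, (_, rm) in enumerate(rms_per_time):
        splits = (
            fixed
            if fixed is not None
            else [
                _draw_split(rm.n_trials, y, test_fraction, rng)
                for _ in range(n_splits)
            ]
        )
        for s, (train, test) in enumerate(splits):
            dec = train_linear_decoder(rm.subset(train), C=C, seed=seed)
            pred = dec.predict(rm.amplitudes[test])
            acc[s, k] = balanced_accuracy(y[test], pred)
    return DecodingResult(
        time_points=times,
        accuracy=acc,
        split_spec="random_80_20",
        n_splits=n_splits,
        seed=seed,
        fov_id=rm0.fov_id,
    )


def cross_generalization_accuracy(
    rms_per_time: list[tuple[float, ResponseMatrix]],
    n_splits: int = 50,
    train_fraction: float = 0.8,
    seed: int = 0,
    C: float = 1.0,
) -> DecodingResult:
    """Train on single-odour trials only, test on mixture trials only.

    Per split, a random ``train_fraction`` of the single-odour trials is
    used for training (target vs other singles); every mixture trial is
    tested, labelled by target presence.
    """
    rm0 = rms_per_time[0][1]
    n_comp = rm0.labels["n_components"].to_numpy()
    singles = np.flatnonzero(n_comp == 1)
    mixtures = np.flatnonzero(n_comp == 2)
    if mixtures.size == 0:
        raise InvalidDesignError("session has no mixture trials to test on")
    if singles.size < 4:
        raise InvalidDesignError("too few single-odour trials to train on")
    y = rm0.labels["target_present"].to_numpy()
    times = np.array([t for t, _ in rms_per_time])
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_fraction * singles.size)))
    subsets = []
    for _ in range(n_splits):
        for _attempt in range(20):
            sub = rng.permutation(singles)[:n_train]
            if np.unique(y[sub]).size == 2:
                subsets.append(sub)
                break
        else:
            raise InvalidTrainingSetError("cannot draw two-class single-odour subset")
    acc = np.empty((n_splits, len(times)))
    for k, (_, rm) in enumerate(rms_per_time):
        for s, sub in enumerate(subsets):
            dec = train_linear_decoder(rm.subset(sub), C=C, seed=seed)
            pred = dec.predict(rm.amplitudes[mixtures])
            acc[s, k] = balanced_accuracy(y[mixtures], pred)
    return DecodingResult(
        time_points=times,
        accuracy=acc,
        split_spec="train_single_test_mixture",
        n_splits=n_splits,
        seed=seed,
        fov_id=rm0.fov_id,
    )


def accuracy_significance(
    results: list[DecodingResult], chance: float = 0.5, alpha: float = 0.05
) -> dict:
    """Earliest time at which field-level accuracy exceeds chance.

    Per time point, a one-sample, one-sided t-test of the field-level mean
    accuracies against ``chance`` (no multiple-comparison correction).
    Requires at least 3 fields.  Returns per-time flags and the earliest
    significant time (None if never).
    """
    if len(results) < 3:
        raise InsufficientReplicatesError(
            f"need >= 3 fields of view, got {len(results)}"
        )
    times = results[0].time_points
    for r in results[1:]:
        if not np.array_equal(r.time_points, times):
            raise InvalidArgumentError("fields have mismatched time points")
    field_means = np.stack([r.mean_timecourse() for r in results])  # fields x time
    p = np.empty(len(times))
    for k in range(len(times)):
        p[k] = stats.ttest_1samp(
            field_means[:, k], chance, alternative="greater"
        ).pvalue
    significant = p < alpha
    earliest = float(times[np.argmax(significant)]) if significant.any() else None
    return {
        "time_points": times,
        "p_values": p,
        "significant": significant,
        "earliest_significant_time": earliest,
        "field_means": field_means,
    }


def _ranksum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation z of the Wilcoxon rank-sum test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n + m) * (n + m - 1.0))
    var = n * m / 12.0 * ((n + m + 1.0) - tie_term)
    if var <= 0:
        log.warning("all samples tied; rank-sum z set to 0")
        return 0.0
    return (w - mu) / np.sqrt(var)


def ranksum_z_timecourse(
    results_a: list[DecodingResult], results_b: list[DecodingResult]
) -> pd.DataFrame:
    """Per-time rank-sum z comparing field-level accuracies of two groups.

    Positive z means group *a*'s accuracies rank higher.  Requires at least
    3 fields per group; swapping the groups flips the sign.
    """
    if len(results_a) < 3 or len(results_b) < 3:
        raise InsufficientReplicatesError("need >= 3 fields per group")
    times = results_a[0].time_points
    a = np.stack([r.mean_timecourse() for r in results_a])
    b = np.stack([r.mean_timecourse() for r in results_b])
    rows = [
        {"time": float(times[k]), "z": _ranksum_z(a[:, k], b[:, k])}
        for k in range(len(times))
    ]
    return pd.DataFrame(rows)
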