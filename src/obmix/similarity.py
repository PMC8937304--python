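"""Trial-by-trial population-vector correlations and the correlation-based
discriminability index.

Each trial's response is a population vector (one amplitude per ROI); the
similarity between two trials is the Pearson correlation of their vectors.
Trials split into the S+ class (target odour present, alone or in a binary
mixture) and the S− class.  The discriminability index is the fraction of
S+ trials whose mean correlation to the other S+ trials exceeds their mean
correlation to the S− trials — equivalently, whose within-class
(1 − r) distance is smaller than the across-class distance.  Ties count as
non-discriminated (strict inequality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedIndexError
from .transients import ResponseMatrix

__all__ = [
    "CorrelationAnalysis",
    "trial_correlation_matrix",
    "class_correlation_summary",
    "discriminability_index",
    "time_resolved_discriminability",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationAnalysis:
    """Trial × trial Pearson correlation matrix with class labels.

    ``kept`` holds the original trial indices retained after excluding
    zero-variance population vectors (Pearson undefined).
    """

    corr: np.ndarray
    class_labels: np.ndarray  # boolean, True = S+
    kept: np.ndarray
    time_point: float | None = None
    fov_id: str = "fov0"

    @property
    def n_trials(self) -> int:
        return self.corr.shape[0]


def trial_correlation_matrix(
    rm: ResponseMatrix, time_point: float | None = None
) -> CorrelationAnalysis:
    """Pearson correlation between every pair of trial population vectors.

    Trials whose amplitude vector is constant across ROIs are excluded
    (with a log entry) because their correlation is undefined.
    """
    if rm.n_rois < 2:
        raise UndefinedIndexError("need at least 2 ROIs for population correlations")
    var = rm.amplitudes.var(axis=1)
    kept = np.flatnonzero(var > 0)
    dropped = np.flatnonzero(var == 0)
    if dropped.size:
        log.warning(
            "excluding %d zero-variance trial vector(s): %s",
            dropped.size,
            dropped.tolist(),
        )
    corr = np.corrcoef(rm.amplitudes[kept])
    corr = np.atleast_2d(corr)
    labels = rm.labels["target_present"].to_numpy()[kept]
    return CorrelationAnalysis(
        corr=corr,
        class_labels=labels.astype(bool),
        kept=kept,
        time_point=time_point,
        fov_id=rm.fov_id,
    )


def class_correlation_summary(ca: CorrelationAnalysis) -> dict:
    """Mean correlation within S+, within S−, and across classes.

    Means run over off-diagonal pairs only, each unordered pair counted
    once.  A class with fewer than 2 trials has an undefined within-class
    mean (NaN).
    """
    pos = np.flatnonzero(ca.class_labels)
    neg = np.flatnonzero(~ca.class_labels)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedIndexError("both classes must be non-empty")

    def off_diag_mean(idx: np.ndarray) -> float:
        if idx.size < 2:
            return float("nan")
        sub = ca.corr[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        return float(sub[iu].mean())

    across = float(ca.corr[np.ix_(pos, neg)].mean())
    return {
        "within_pos": off_diag_mean(pos),
        "within_neg": off_diag_mean(neg),
        "across": across,
    }


def discriminability_index(ca: CorrelationAnalysis) -> float:
    """Fraction of S+ trials better correlated with their own class.

    For each S+ trial, its mean correlation to the *other* S+ trials is
    compared with its mean correlation to all S− trials; the index is the
    fraction for which within > across (strict; ties fail).  Ranges [0, 1];
    chance is 0.5 for exchangeable classes.
    """
    pos = np.flatnonzero(ca.class_labels)
    neg = np.flatnonzero(~ca.class_labels)
    if pos.size < 2 or neg.size < 1:
        raise UndefinedIndexError(
            f"need >= 2 S+ and >= 1 S- trials, got {pos.size} and {neg.size}"
        )
    wins = 0
    for i in pos:
        others = pos[pos != i]
        within = ca.corr[i, others].mean()
        across = ca.corr[i, neg].mean()
        if within > across:
            wins += 1
    return wins / pos.size


def time_resolved_discriminability(
    cas: list[CorrelationAnalysis],
) -> pd.DataFrame:
    """Discriminability index per time point, as a tidy table."""
    rows = []
    for ca in cas:
        rows.append(
            {
                "time": ca.time_point,
                "metric": "discriminability_index",
                "value": discriminability_index(ca),
                "fov_id": ca.fov_id,
            }
        )
    return pd.DataFrame(rows)
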