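"""Go/No-Go behavioural metrics: response classification, learning curves,
and the lick preference index.

A trial's choice is read out from anticipatory licks — beam breaks within
the 3 s between final-valve onset and reward delivery.  With the lick
threshold at 2, the correct response on rewarded trials is two or more
licks, and on unrewarded trials one lick or less.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, UndefinedIndexError

__all__ = [
    "BehaviourTrial",
    "classify_response",
    "learning_curve",
    "lick_preference_index",
]


@dataclass(frozen=True)
class BehaviourTrial:
    """One Go/No-Go trial: anticipatory lick count, reward flag, stimulus."""

    anticipatory_licks: int
    rewarded: bool
    stimulus: tuple[str, ...] = ()
    background_id: str = ""

    def __post_init__(self) -> None:
        if self.anticipatory_licks < 0:
            raise InvalidArgumentError("lick count must be >= 0")


def classify_response(trial: BehaviourTrial, threshold: int = 2) -> str:
    """Classify a trial as hit / miss / false_alarm / correct_rejection.

    Rewarded trials: >= ``threshold`` licks is a hit, fewer a miss.
    Unrewarded trials: <= ``threshold - 1`` licks is a correct rejection,
    more a false alarm.
    """
    if trial.rewarded:
        return "hit" if trial.anticipatory_licks >= threshold else "miss"
    return (
        "correct_rejection"
        if trial.anticipatory_licks <= threshold - 1
        else "false_alarm"
    )


def learning_curve(
    trials: Sequence[BehaviourTrial],
    block: int = 50,
    threshold: int = 2,
    criterion: float = 0.8,
) -> dict:
    """Blockwise accuracy over consecutive, non-overlapping 50-trial blocks.

    Accuracy per block is (hits + correct rejections) / block.  Returns the
    block accuracies, the trailing partial block's accuracy (reported
    separately, never mixed in), and ``trials_to_criterion``: the end index
    (1-based trial count) of the first block whose accuracy meets the
    criterion, or None if never reached.
    """
    if block < 1:
        raise InvalidArgumentError("block size must be >= 1")
    correct = np.array(
        [classify_response(t, threshold) in ("hit", "correct_rejection")
         for t in trials],
        dtype=float,
    )
    n_full = len(correct) // block
    if n_full < 1:
        raise InvalidArgumentError(
            f"need at least one full block of {block} trials, got {len(correct)}"
        )
    accuracies = correct[: n_full * block].reshape(n_full, block).mean(axis=1)
    partial = correct[n_full * block :]
    trials_to_criterion = None
    for i, a in enumerate(accuracies):
        if a >= criterion:
            trials_to_criterion = (i + 1) * block
            break
    return {
        "block_accuracy": accuracies,
        "partial_block_accuracy": float(partial.mean()) if partial.size else None,
        "trials_to_criterion": trials_to_criterion,
    }


def lick_preference_index(
    trials: Sequence[BehaviourTrial],
) -> pd.DataFrame:
    """Per-background lick preference index.

    For each background odour the index is
    ``(L_rew − L_unrew) / (L_rew + L_unrew)`` where ``L_rew`` and
    ``L_unrew`` are the mean anticipatory-lick counts on rewarded and
    unrewarded trials with that background.  The index lies in [−1, 1];
    1 means all anticipatory licks were observed on rewarded trials only.

    Raises
    ------
    UndefinedIndexError
        If a background lacks rewarded or unrewarded trials, or both mean
        lick counts are zero (the ratio is then undefined).
    """
    rows = []
    by_bg: dict[str, list[BehaviourTrial]] = {}
    for t in trials:
        by_bg.setdefault(t.background_id, []).append(t)
    for bg in sorted(by_bg):
        group = by_bg[bg]
        rew = [t.anticipatory_licks for t in group if t.rewarded]
        unrew = [t.anticipatory_licks for t in group if not t.rewarded]
        if not rew or not unrew:
            raise UndefinedIndexError(
                f"background {bg!r} needs both rewarded and unrewarded trials"
            )
        l_r, l_u = float(np.mean(rew)), float(np.mean(unrew))
        if l_r + l_u == 0:
            raise UndefinedIndexError(
                f"background {bg!r}: both mean lick counts are zero"
            )
        rows.append(
            {
                "background_id": bg,
                "lick_rewarded": l_r,
                "lick_unrewarded": l_u,
                "preference_index": (l_r - l_u) / (l_r + l_u),
                "n_rewarded": len(rew),
                "n_unrewarded": len(unrew),
            }
        )
    return pd.DataFrame(rows)
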