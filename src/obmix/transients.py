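"""ΔF/F conversion and window-averaged response amplitudes.

A trial is an ROI × frame fluorescence matrix with stimulus metadata.  The
conventions used throughout the package:

* frames are 0-based; ``onset_frame`` is the first frame at which the final
  valve is open (stimulus onset);
* times are seconds relative to stimulus onset;
* analysis windows ``(start_s, end_s)`` are half-open in frames,
  ``[onset + round(start * rate), onset + round(end * rate))``.

The default response window is the first second after onset (30 frames at
30 Hz); the default baseline for ΔF/F is the 2 s preceding onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateBaselineError,
    InvalidArgumentError,
    ShapeMismatchError,
)

__all__ = [
    "TrialRecording",
    "ResponseMatrix",
    "compute_dff",
    "response_amplitude",
    "build_response_matrix",
    "time_resolved_matrices",
]


@dataclass
class TrialRecording:
    """One trial's fluorescence traces plus stimulus/state metadata.

    ``fluorescence`` has shape (n_rois, n_frames) and holds either raw
    fluorescence (``is_dff=False``) or ΔF/F (``is_dff=True``).  ``stimulus``
    is the tuple of odour component labels (length 1 for single odours,
    2 for binary mixtures).
    """

    fluorescence: np.ndarray
    frame_rate_hz: float
    onset_frame: int
    stimulus: tuple[str, ...]
    state: str = "unspecified"
    fov_id: str = "fov0"
    rewarded: bool | None = None
    is_dff: bool = True

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ShapeMismatchError(
                f"fluorescence must be ROI x frame (2-D), got {self.fluorescence.ndim}-D"
            )
        if not 0 <= self.onset_frame < self.n_frames:
            raise InvalidArgumentError(
                f"onset_frame {self.onset_frame} outside [0, {self.n_frames})"
            )
        self.stimulus = tuple(self.stimulus)

    @property
    def n_rois(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    def frame_index(self, t_s: float) -> int:
        """Frame index for a time in seconds relative to onset (rounded)."""
        return self.onset_frame + int(round(t_s * self.frame_rate_hz))


@dataclass
class ResponseMatrix:
    """Trials × ROIs window-averaged amplitudes with per-trial labels.

    ``labels`` is a DataFrame with one row per trial and columns
    ``stimulus`` (components joined by '+'), ``n_components``,
    ``target_present`` and ``masker_present``.
    """

    amplitudes: np.ndarray
    labels: pd.DataFrame
    window: tuple[float, float]
    fov_id: str = "fov0"
    state: str = "unspecified"
    stimuli: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.labels) != self.amplitudes.shape[0]:
            raise ShapeMismatchError(
                f"{len(self.labels)} labels for {self.amplitudes.shape[0]} trials"
            )

    @property
    def n_trials(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_rois(self) -> int:
        return self.amplitudes.shape[1]

    def trials_with_stimulus(self, *components: str) -> np.ndarray:
        """Row indices of trials whose stimulus is exactly these components."""
        key = tuple(sorted(components))
        return np.array(
            [i for i, s in enumerate(self.stimuli) if tuple(sorted(s)) == key],
            dtype=int,
        )

    def subset(self, idx: np.ndarray) -> "ResponseMatrix":
        idx = np.asarray(idx, dtype=int)
        return ResponseMatrix(
            amplitudes=self.amplitudes[idx],
            labels=self.labels.iloc[idx].reset_index(drop=True),
            window=self.window,
            fov_id=self.fov_id,
            state=self.state,
            stimuli=[self.stimuli[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Export as a tidy table: label columns followed by one column per ROI."""
        roi_cols = pd.DataFrame(
            self.amplitudes,
            columns=[f"roi{j:03d}" for j in range(self.n_rois)],
        )
        return pd.concat([self.labels.reset_index(drop=True), roi_cols], axis=1)


def _window_frames(
    onset_frame: int, frame_rate_hz: float, window: tuple[float, float]
) -> tuple[int, int]:
    start = onset_frame + int(round(window[0] * frame_rate_hz))
    stop = onset_frame + int(round(window[1] * frame_rate_hz))
    return start, stop


def compute_dff(trial: TrialRecording, baseline_s: float = 2.0) -> TrialRecording:
    """Convert raw fluorescence to ΔF/F against a pre-onset baseline.

    The baseline F0 is the per-ROI mean over the ``baseline_s`` seconds
    immediately preceding the final-valve onset; the output trace is
    (F − F0)/F0.  Trials already flagged as ΔF/F are returned unchanged.

    Raises
    ------
    DegenerateBaselineError
        If any ROI's baseline mean is ≤ 0 (names the offending ROI).
    """
    if trial.is_dff:
        return trial
    n_base = int(round(baseline_s * trial.frame_rate_hz))
    if n_base <= 0:
        raise InvalidArgumentError(f"baseline_s={baseline_s} gives an empty window")
    if n_base > trial.onset_frame:
        raise InvalidArgumentError(
            f"baseline of {n_base} frames does not fit before onset frame "
            f"{trial.onset_frame}"
        )
    base = trial.fluorescence[:, trial.onset_frame - n_base : trial.onset_frame]
    f0 = base.mean(axis=1)
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise DegenerateBaselineError(
            f"non-positive baseline fluorescence for ROI(s) {bad.tolist()}"
        )
    dff = (trial.fluorescence - f0[:, None]) / f0[:, None]
    return replace(trial, fluorescence=dff, is_dff=True)


def response_amplitude(
    trial: TrialRecording, window: tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Per-ROI mean ΔF/F over a half-open window relative to onset.

    The default (0, 1) s window is 30 frames at 30 frames/s.
    """
    start, stop = _window_frames(trial.onset_frame, trial.frame_rate_hz, window)
    if stop <= start:
        raise InvalidArgumentError(f"window {window} contains no frames")
    if start < 0 or stop > trial.n_frames:
        raise InvalidArgumentError(
            f"window {window} -> frames [{start}, {stop}) outside recording "
            f"of {trial.n_frames} frames"
        )
    return trial.fluorescence[:, start:stop].mean(axis=1)


def build_response_matrix(
    trials: Sequence[TrialRecording],
    window: tuple[float, float] = (0.0, 1.0),
    target: str | None = None,
    masker: str | None = None,
) -> ResponseMatrix:
    """Assemble a trials × ROIs amplitude matrix, preserving trial order.

    ``target_present`` is true when the target odour is among a trial's
    components; ``masker_present`` likewise for the masker.
    """
    if not trials:
        raise InvalidArgumentError("no trials given")
    n_rois = trials[0].n_rois
    fov = trials[0].fov_id
    for k, t in enumerate(trials):
        if t.n_rois != n_rois:
            raise ShapeMismatchError(
                f"trial {k} has {t.n_rois} ROIs, expected {n_rois}"
            )
        if t.fov_id != fov:
            raise ShapeMismatchError(
                f"trial {k} is from field {t.fov_id!r}, expected {fov!r}"
            )
    amps = np.stack([response_amplitude(t, window) for t in trials])
    stimuli = [t.stimulus for t in trials]
    labels = pd.DataFrame(
        {
            "stimulus": ["+".join(s) for s in stimuli],
            "n_components": [len(s) for s in stimuli],
            "target_present": [target in s if target else False for s in stimuli],
            "masker_present": [masker in s if masker else False for s in stimuli],
            "rewarded": [t.rewarded for t in trials],
        }
    )
    return ResponseMatrix(
        amplitudes=amps,
        labels=labels,
        window=window,
        fov_id=fov,
        state=trials[0].state,
        stimuli=stimuli,
    )


def time_resolved_matrices(
    trials: Sequence[TrialRecording],
    target: str | None = None,
    masker: str | None = None,
    window_s: float = 1.0,
    step_s: float = 0.25,
    t_start: float = -1.0,
    t_end: float = 3.5,
) -> list[tuple[float, ResponseMatrix]]:
    """Sliding-window response matrices for time-course analyses.

    Each time point ``t`` labels the CENTRE of a ``window_s``-long window
    (``window_s`` = 30 frames at 30 Hz by default), stepped by ``step_s``
    from ``t_start`` to ``t_end`` inclusive.  Returns (time, matrix) pairs.
    """
    if window_s <= 0 or step_s <= 0:
        raise InvalidArgumentError("window_s and step_s must be positive")
    out: list[tuple[float, ResponseMatrix]] = []
    n_steps = int(round((t_end - t_start) / step_s))
    for k in range(n_steps + 1):
        t = t_start + k * step_s
        win = (t - window_s / 2.0, t + window_s / 2.0)
        out.append((round(t, 6), build_response_matrix(trials, win, target, masker)))
    return out
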