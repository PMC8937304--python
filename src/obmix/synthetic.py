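"""Synthetic ROI calcium responses and behavioural trials.

This module generates populations of olfactory-bulb output-neuron responses
with the statistical structure the downstream analyses assume, so the whole
pipeline is testable without any recorded data:

* an odour panel with graded tuning overlap to a target odour (the target's
  strongest masker having the most similar glomerular pattern);
* single-odour and binary-mixture trials at 30 frames/s, 400 frames per
  trial with 200 baseline frames before the final-valve onset;
* state-dependent response gain, trial-to-trial noise, and mixture
  summation that is either linear or saturating (the odd-sigmoid
  normalisation of :mod:`obmix.sublinearity`);
* Go/No-Go behavioural trials with per-class correct-response rates and
  Poisson lick counts.

All randomness flows through explicit integer seeds; no global RNG state is
touched.  Amplitudes are in ΔF/F units.  Per-ROI response-amplitude scales
are order-of-magnitude choices (real per-ROI amplitude distributions are
not published for this preparation); see the presets' docstrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .behaviour import BehaviourTrial
from .exceptions import InvalidArgumentError, UnsupportedStimulusError
from .sublinearity import NormalisationParams, REFERENCE_PARAMS, normalise
from .transients import TrialRecording

__all__ = [
    "OdourPanel",
    "StateProfile",
    "SyntheticConfig",
    "STATE_PRESETS",
    "DEFAULT_ODOUR_IDS",
    "DEFAULT_OVERLAPS",
    "make_panel",
    "make_trial_list",
    "simulate_session",
    "simulate_behaviour",
    "make_study_fields",
]

#: Default 11-odour panel: a target ester, its closest masker, and further
#: odours of decreasing pattern overlap with the target.
DEFAULT_ODOUR_IDS = (
    "EB", "MB", "EA", "MA", "PA", "IA", "EP", "HX", "AA", "BZ", "LM",
)

#: Target-overlap spectrum for the ten background odours of the default
#: panel (the masker MB overlapping most), before any state-dependent
#: decorrelation scaling.
DEFAULT_OVERLAPS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.0)


@dataclass
class OdourPanel:
    """Odour identities and the ROI × odour tuning (mean amplitude) matrix."""

    odour_ids: list[str]
    target_id: str
    tuning: np.ndarray  # n_rois x n_odours, ΔF/F
    overlap_spectrum: dict[str, float]

    def __post_init__(self) -> None:
        if self.target_id not in self.odour_ids:
            raise InvalidArgumentError(
                f"target {self.target_id!r} not in panel {self.odour_ids}"
            )
        self.tuning = np.asarray(self.tuning, dtype=float)
        if not np.all(np.isfinite(self.tuning)):
            raise InvalidArgumentError("tuning matrix contains non-finite values")
        if self.tuning.shape[1] != len(self.odour_ids):
            raise InvalidArgumentError("tuning has wrong number of odour columns")

    @property
    def n_rois(self) -> int:
        return self.tuning.shape[0]

    def tuning_for(self, odour: str) -> np.ndarray:
        return self.tuning[:, self.odour_ids.index(odour)]

    @property
    def masker_id(self) -> str:
        """The background odour with the highest requested target overlap."""
        return max(self.overlap_spectrum, key=self.overlap_spectrum.get)


@dataclass(frozen=True)
class StateProfile:
    """Brain-state preset: gain, noise, summation rule and response kinetics.

    ``summation`` is either the string ``"linear"`` or a
    :class:`NormalisationParams` applied to the summed component tuning of a
    mixture.  ``overlap_scale`` multiplies the panel's overlap spectrum when
    building state-matched fields (awake patterns are more decorrelated).
    """

    name: str
    gain: float
    trial_noise_sd: float
    summation: Union[str, NormalisationParams] = "linear"
    onset_lag_s: float = 0.1
    decay_tau_s: float = 2.0
    overlap_scale: float = 1.0
    #: SD of the per-ROI (frozen within a session) multiplicative diversity
    #: of mixture suppression; 0 means every ROI follows the summation rule
    #: exactly.  Real populations show a broad spread of mixture
    #: interactions around the typical suppression, so the saturating preset
    #: uses a nonzero value.
    summation_heterogeneity: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidArgumentError(f"gain must be > 0, got {self.gain}")
        if self.trial_noise_sd < 0:
            raise InvalidArgumentError(
                f"trial_noise_sd must be >= 0, got {self.trial_noise_sd}"
            )
        if isinstance(self.summation, str) and self.summation != "linear":
            raise InvalidArgumentError(
                f"summation must be 'linear' or NormalisationParams, got "
                f"{self.summation!r}"
            )


#: State presets.  Gains and noise follow the motivating observations:
#: anaesthetised responses are large, reliable (trial SD 0.2 ΔF/F) and sum
#: sublinearly (saturating sigmoid, Rmax = 6, s = 0.2); awake behaving
#: responses are dampened (gain 0.4), far more variable (trial SD 2 ΔF/F),
#: sum linearly in the early phase, and ride on more decorrelated patterns.
#: Anaesthetised transients are slow and sustained; awake ones decay faster.
STATE_PRESETS: dict[str, StateProfile] = {
    "anaesthetised": StateProfile(
        name="anaesthetised",
        gain=1.0,
        trial_noise_sd=0.2,
        summation=REFERENCE_PARAMS,
        onset_lag_s=0.1,
        decay_tau_s=6.0,
        overlap_scale=1.0,
        summation_heterogeneity=0.5,
    ),
    "behaving": StateProfile(
        name="behaving",
        gain=0.4,
        trial_noise_sd=2.0,
        summation="linear",
        onset_lag_s=0.05,
        decay_tau_s=1.5,
        overlap_scale=0.5,
    ),
    "naive_engaged": StateProfile(
        name="naive_engaged",
        gain=0.5,
        trial_noise_sd=1.5,
        summation="linear",
        onset_lag_s=0.05,
        decay_tau_s=1.5,
        overlap_scale=0.6,
    ),
    "naive_disengaged": StateProfile(
        name="naive_disengaged",
        gain=0.7,
        trial_noise_sd=1.2,
        summation="linear",
        onset_lag_s=0.05,
        decay_tau_s=2.0,
        overlap_scale=1.0,
    ),
}


@dataclass
class SyntheticConfig:
    """Acquisition geometry and trial list for one simulated session.

    Defaults mirror the acquisition protocol: 400 frames at 30 frames/s with
    200 baseline frames before the final-valve opening and a 0.5 s stimulus.
    ``frame_noise_sd`` is small per-frame imaging noise; ``gain_jitter_sd``
    is an optional per-trial shared multiplicative gain term (default off).
    If ``baseline_f`` is set, trials are emitted as raw fluorescence
    ``baseline_f * (1 + ΔF/F)`` instead of ΔF/F.
    """

    n_rois: int = 100
    frame_rate_hz: float = 30.0
    n_frames: int = 400
    onset_frame: int = 200
    stim_duration_s: float = 0.5
    trial_list: list[tuple[str, ...]] = field(default_factory=list)
    seed: int = 0
    frame_noise_sd: float = 0.02
    gain_jitter_sd: float = 0.0
    rise_tau_s: float = 0.1
    baseline_f: float | None = None
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        if not 0 <= self.onset_frame < self.n_frames:
            raise InvalidArgumentError(
                f"onset_frame {self.onset_frame} outside [0, {self.n_frames})"
            )
        if self.frame_noise_sd < 0 or self.gain_jitter_sd < 0:
            raise InvalidArgumentError("noise SDs must be >= 0")


def make_panel(
    n_rois: int,
    n_odours: int,
    target_overlaps: Sequence[float],
    seed: int,
    odour_ids: Sequence[str] | None = None,
    amp_mean: float = 2.5,
    amp_sd: float = 2.0,
) -> OdourPanel:
    """Generate an odour panel whose background tunings have prescribed
    Pearson correlations with the target tuning.

    Background tuning vectors are built in standardised space as
    ``rho * z_target + sqrt(1 - rho^2) * z_perp`` with ``z_perp`` the
    empirically orthogonalised residual of an independent draw, so the
    realised correlation over ROIs equals the requested overlap exactly;
    vectors are then mapped to amplitude units (mean ``amp_mean``, SD
    ``amp_sd`` ΔF/F).  The first odour id is the target.
    """
    overlaps = np.asarray(target_overlaps, dtype=float)
    if not np.all(np.isfinite(overlaps)):
        raise InvalidArgumentError("target_overlaps contains non-finite values")
    if np.any((overlaps < 0) | (overlaps > 1)):
        raise InvalidArgumentError("target_overlaps must lie in [0, 1]")
    if n_odours != len(overlaps) + 1:
        raise InvalidArgumentError(
            f"n_odours ({n_odours}) must be len(target_overlaps) + 1 "
            f"({len(overlaps) + 1})"
        )
    if n_rois < 3:
        raise InvalidArgumentError("need at least 3 ROIs")
    if odour_ids is None:
        odour_ids = [DEFAULT_ODOUR_IDS[i] if i < len(DEFAULT_ODOUR_IDS) else f"OD{i}"
                     for i in range(n_odours)]
    odour_ids = list(odour_ids)

    rng = np.random.default_rng(seed)

    def standardise(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / v.std()

    z_t = standardise(rng.standard_normal(n_rois))
    cols = [z_t]
    for rho in overlaps:
        raw = rng.standard_normal(n_rois)
        resid = raw - raw.mean() - (np.dot(raw, z_t) / np.dot(z_t, z_t)) * z_t
        z_p = standardise(resid)
        cols.append(rho * z_t + np.sqrt(max(0.0, 1.0 - rho**2)) * z_p)
    z = np.column_stack(cols)
    tuning = amp_mean + amp_sd * z
    spectrum = {odour_ids[i + 1]: float(overlaps[i]) for i in range(len(overlaps))}
    return OdourPanel(
        odour_ids=odour_ids, target_id=odour_ids[0], tuning=tuning,
        overlap_spectrum=spectrum,
    )


def make_trial_list(
    panel: OdourPanel,
    n_blocks: int = 6,
    seed: int = 0,
    shuffle_within_block: bool = True,
) -> list[tuple[str, ...]]:
    """Compose a session as blocks of 10 trials.

    Every 10-trial block contains the target, the masker, and their mixture
    (the scheduled core trials), plus one target+other mixture, four other
    single odours, and two non-target mixtures — so the session carries
    single-odour and mixture trials of both classes for every analysis.
    """
    rng = np.random.default_rng(seed)
    target = panel.target_id
    masker = panel.masker_id
    others = [o for o in panel.odour_ids if o not in (target, masker)]
    trials: list[tuple[str, ...]] = []
    for _ in range(n_blocks):
        block: list[tuple[str, ...]] = [
            (target,),
            (masker,),
            (target, masker),
        ]
        x = rng.choice(others)
        block.append((target, str(x)))
        singles = rng.choice(others, size=4, replace=False)
        block.extend((str(s),) for s in singles)
        for _ in range(2):
            a, b = rng.choice(others, size=2, replace=False)
            block.append((str(a), str(b)))
        if shuffle_within_block:
            order = rng.permutation(len(block))
            block = [block[i] for i in order]
        trials.extend(block)
    return trials


def _transient_kernel(cfg: SyntheticConfig, state: StateProfile) -> np.ndarray:
    """Difference-of-exponentials transient, unit mean over the 1-s response window."""
    t = (np.arange(cfg.n_frames) - cfg.onset_frame) / cfg.frame_rate_hz
    t = t - state.onset_lag_s
    k = np.where(
        t > 0,
        np.exp(-np.clip(t, 0, None) / state.decay_tau_s)
        - np.exp(-np.clip(t, 0, None) / cfg.rise_tau_s),
        0.0,
    )
    win = slice(cfg.onset_frame, cfg.onset_frame + int(round(cfg.frame_rate_hz)))
    scale = k[win].mean()
    if scale <= 0:
        raise InvalidArgumentError(
            "transient kernel has non-positive mean over the response window; "
            "check onset_lag_s / decay_tau_s"
        )
    return k / scale


def _mean_amplitude(
    panel: OdourPanel,
    state: StateProfile,
    stimulus: tuple[str, ...],
    heterogeneity: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free per-ROI response amplitude for one stimulus under a state.

    ``heterogeneity`` is the per-ROI multiplicative diversity of mixture
    suppression (frozen within a session): each ROI's deviation from the
    linear sum is scaled by ``1 + h_i``, so the population spreads around
    the summation rule instead of following it identically.
    """
    if len(stimulus) == 1:
        return state.gain * panel.tuning_for(stimulus[0])
    if len(stimulus) == 2:
        s = panel.tuning_for(stimulus[0]) + panel.tuning_for(stimulus[1])
        if isinstance(state.summation, NormalisationParams):
            out = normalise(s, state.summation)
            if heterogeneity is not None:
                out = s + (1.0 + heterogeneity) * (out - s)
            return state.gain * out
        return state.gain * s
    raise UnsupportedStimulusError(
        f"mixtures with {len(stimulus)} components are not supported"
    )


def simulate_session(
    panel: OdourPanel, state: StateProfile, cfg: SyntheticConfig
) -> list[TrialRecording]:
    """Simulate one field of view's session as a list of trial recordings.

    Each trial's amplitude is ``gain × (tuning sum, transformed per the
    state's summation rule for mixtures) + N(0, trial_noise_sd)`` per ROI;
    the transient is a difference of exponentials scaled so its mean over
    the first post-onset second equals that amplitude, plus independent
    per-frame Gaussian imaging noise.  Identical (panel, state, cfg) —
    including ``cfg.seed`` — give bit-identical output.
    """
    for stim in cfg.trial_list:
        for o in stim:
            if o not in panel.odour_ids:
                raise InvalidArgumentError(f"stimulus odour {o!r} not in panel")
    rng = np.random.default_rng(cfg.seed)
    kernel = _transient_kernel(cfg, state)
    het = (
        rng.normal(0.0, state.summation_heterogeneity, size=panel.n_rois)
        if state.summation_heterogeneity > 0
        else None
    )
    trials = []
    for stim in cfg.trial_list:
        amp = _mean_amplitude(panel, state, stim, heterogeneity=het)
        if state.trial_noise_sd > 0:
            amp = amp + rng.normal(0.0, state.trial_noise_sd, size=panel.n_rois)
        if cfg.gain_jitter_sd > 0:
            amp = amp * (1.0 + rng.normal(0.0, cfg.gain_jitter_sd))
        dff = amp[:, None] * kernel[None, :]
        if cfg.frame_noise_sd > 0:
            dff = dff + rng.normal(0.0, cfg.frame_noise_sd, size=dff.shape)
        if cfg.baseline_f is not None:
            trace = cfg.baseline_f * (1.0 + dff)
            is_dff = False
        else:
            trace = dff
            is_dff = True
        trials.append(
            TrialRecording(
                fluorescence=trace,
                frame_rate_hz=cfg.frame_rate_hz,
                onset_frame=cfg.onset_frame,
                stimulus=stim,
                state=state.name,
                fov_id=cfg.fov_id,
                rewarded=(panel.target_id in stim) or None,
                is_dff=is_dff,
            )
        )
    return trials


def make_study_fields(
    state_name: str,
    n_fields: int,
    seed: int,
    n_rois: int = 100,
    n_blocks: int = 6,
) -> list[list[TrialRecording]]:
    """Simulate several fields of view under one state preset.

    Each field gets its own panel (fresh tuning, overlap spectrum scaled by
    the state's ``overlap_scale``) and its own trial schedule; sub-seeds are
    spawned deterministically from ``seed``.
    """
    state = STATE_PRESETS[state_name]
    ss = np.random.SeedSequence(seed)
    fields = []
    for i, child in enumerate(ss.spawn(n_fields)):
        s1, s2, s3 = child.generate_state(3) % (2**31)
        overlaps = tuple(v * state.overlap_scale for v in DEFAULT_OVERLAPS)
        panel = make_panel(
            n_rois, len(DEFAULT_ODOUR_IDS), overlaps, seed=int(s1)
        )
        cfg = SyntheticConfig(
            n_rois=n_rois,
            trial_list=make_trial_list(panel, n_blocks=n_blocks, seed=int(s2)),
            seed=int(s3),
            fov_id=f"{state_name}_f{i:02d}",
        )
        fields.append(simulate_session(panel, state, cfg))
    return fields


def simulate_behaviour(
    n_trials: int,
    p_correct,
    lick_rate_rewarded: float,
    lick_rate_unrewarded: float,
    seed: int,
    backgrounds: Sequence[str] | None = None,
    target: str = "EB",
    p_rewarded: float = 1.0 / 3.0,
) -> list[BehaviourTrial]:
    """Simulate Go/No-Go trials with per-class correct-response probabilities.

    ``p_correct`` is a scalar or a dict mapping background id to the
    probability of a correct choice on trials with that background.  Lick
    counts within the 3-s response window are Poisson: hits produce
    ``max(2, Poisson(lick_rate_rewarded))`` licks; correct rejections and
    misses produce ``min(1, Poisson(lick_rate_unrewarded))``; false alarms
    produce ``2 + Poisson(lick_rate_unrewarded)`` (so with a zero unrewarded
    lick rate and perfect performance, all anticipatory licks fall on
    rewarded trials and the lick preference index is exactly 1).
    """
    if lick_rate_rewarded < 0 or lick_rate_unrewarded < 0:
        raise InvalidArgumentError("lick rates must be >= 0")
    if backgrounds is None:
        backgrounds = [o for o in DEFAULT_ODOUR_IDS if o != target]

    def p_for(b: str) -> float:
        p = p_correct[b] if isinstance(p_correct, dict) else p_correct
        if not 0.0 <= p <= 1.0:
            raise InvalidArgumentError(f"p_correct for {b!r} is {p}, outside [0, 1]")
        return float(p)

    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        b = backgrounds[i % len(backgrounds)]
        rewarded = bool(rng.random() < p_rewarded)
        correct = bool(rng.random() < p_for(b))
        if rewarded:
            if correct:  # hit
                licks = max(2, int(rng.poisson(lick_rate_rewarded)))
            else:  # miss
                licks = min(1, int(rng.poisson(lick_rate_unrewarded)))
            stimulus = (target, b)
        else:
            if correct:  # correct rejection
                licks = min(1, int(rng.poisson(lick_rate_unrewarded)))
            else:  # false alarm
                licks = 2 + int(rng.poisson(lick_rate_unrewarded))
            stimulus = (b,)
        trials.append(
            BehaviourTrial(
                anticipatory_licks=licks,
                rewarded=rewarded,
                stimulus=stimulus,
                background_id=b,
            )
        )
    return trials
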