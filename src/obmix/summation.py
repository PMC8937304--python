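"""Mixture-summation linearity: masking index, fractional deviation,
joint-SEM deviation, per-field medians, and noise robustness.

The central comparison is per ROI between the observed mean mixture
response and the linear sum of the trial-averaged component responses.
Two normalisations of the difference are used:

* *fractional deviation*: (R_observed − R_linear) / |R_linear| — negative
  values indicate sublinear (suppressive) summation;
* *deviation from linearity*: (R_observed − R_linear) /
  (sem_observed + sem_linear) — values beyond ±2 classify an ROI as
  summing nonlinearly (below −2: sublinearly).

ROIs whose |R_linear| falls below a configurable floor (default 0.05 ΔF/F)
are excluded from fractional deviation, because the ratio is unstable near
zero; exclusions surface as NaN and are dropped (with counts) by the
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EmptyFieldError,
    InsufficientTrialsError,
    InvalidArgumentError,
    NoReferenceGlomeruliError,
    UndefinedIndexError,
)
from .transients import ResponseMatrix

__all__ = [
    "SummationPair",
    "MaskingResult",
    "DEFAULT_EXCLUSION_FLOOR",
    "linear_sum_pairs",
    "fractional_deviation",
    "deviation_from_linearity",
    "classify_linearity",
    "median_fractional_deviation",
    "noise_robustness",
    "masking_index",
    "pairs_to_frame",
]

#: |R_linear| below this (ΔF/F) excludes an ROI from fractional deviation.
DEFAULT_EXCLUSION_FLOOR = 0.05


@dataclass(frozen=True)
class SummationPair:
    """Per-ROI observed-mixture vs linear-sum amplitudes with dispersion."""

    roi_id: int
    r_observed: float
    r_linear: float
    sem_observed: float
    sem_linear: float
    n_trials_mixture: int
    n_trials_components: int
    fov_id: str = "fov0"

    def __post_init__(self) -> None:
        if self.sem_observed < 0 or self.sem_linear < 0:
            raise InvalidArgumentError("SEMs must be >= 0")
        if not (math.isfinite(self.r_observed) and math.isfinite(self.r_linear)):
            raise InvalidArgumentError("means must be finite")


@dataclass(frozen=True)
class MaskingResult:
    """Masking index of one background odour against the target pattern."""

    odour_id: str
    masking_index: float
    n_target_glomeruli: int


def linear_sum_pairs(
    rm: ResponseMatrix, component_a: str, component_b: str
) -> list[SummationPair]:
    """Build per-ROI (observed mixture, linear sum) pairs for one mixture.

    ``R_linear`` is the sum of the trial-averaged single-component
    responses; its SEM is the sum of the component SEMs (joint SEM).
    ``R_observed`` averages the mixture trials.
    """
    idx_a = rm.trials_with_stimulus(component_a)
    idx_b = rm.trials_with_stimulus(component_b)
    idx_mix = rm.trials_with_stimulus(component_a, component_b)
    for name, idx in (
        (component_a, idx_a),
        (component_b, idx_b),
        (f"{component_a}+{component_b}", idx_mix),
    ):
        if idx.size < 1:
            raise InsufficientTrialsError(f"no trials of stimulus {name!r}")
    a = rm.amplitudes[idx_a]
    b = rm.amplitudes[idx_b]
    mix = rm.amplitudes[idx_mix]

    def sem(x: np.ndarray) -> np.ndarray:
        if x.shape[0] < 2:
            return np.zeros(x.shape[1])
        return stats.sem(x, axis=0)

    r_lin = a.mean(axis=0) + b.mean(axis=0)
    sem_lin = sem(a) + sem(b)
    r_obs = mix.mean(axis=0)
    sem_obs = sem(mix)
    n_comp = min(idx_a.size, idx_b.size)
    return [
        SummationPair(
            roi_id=j,
            r_observed=float(r_obs[j]),
            r_linear=float(r_lin[j]),
            sem_observed=float(sem_obs[j]),
            sem_linear=float(sem_lin[j]),
            n_trials_mixture=int(idx_mix.size),
            n_trials_components=int(n_comp),
            fov_id=rm.fov_id,
        )
        for j in range(rm.n_rois)
    ]


def fractional_deviation(
    pair: SummationPair, floor: float = DEFAULT_EXCLUSION_FLOOR
) -> float:
    """(R_observed − R_linear) / |R_linear|; NaN marks an excluded ROI.

    Negative values indicate sublinear summation.  ROIs with
    |R_linear| < ``floor`` are excluded (returned as NaN) because the ratio
    is unstable near zero.
    """
    if abs(pair.r_linear) < floor:
        return math.nan
    return (pair.r_observed - pair.r_linear) / abs(pair.r_linear)


def deviation_from_linearity(pair: SummationPair) -> float:
    """(R_observed − R_linear) / (sem_observed + sem_linear).

    |value| > 2 classifies the ROI as summing nonlinearly; value < −2 as
    sublinearly.  A zero joint SEM makes the deviation undefined (NaN),
    unless the numerator is also zero (exactly linear, returns 0).
    """
    num = pair.r_observed - pair.r_linear
    den = pair.sem_observed + pair.sem_linear
    if den == 0:
        # noiseless data: exact linearity up to float rounding is 0, else undefined
        tol = 1e-9 * max(1.0, abs(pair.r_linear))
        return 0.0 if abs(num) <= tol else math.nan
    return num / den


def classify_linearity(
    pairs: list[SummationPair], threshold: float = 2.0
) -> pd.DataFrame:
    """Classify each ROI by its joint-SEM deviation.

    Returns a table with the deviation and a label in
    {linear, sublinear, supralinear, undefined}; |dev| > threshold is
    nonlinear, with the sign choosing sub vs supra.
    """
    rows = []
    for p in pairs:
        d = deviation_from_linearity(p)
        if math.isnan(d):
            label = "undefined"
        elif d < -threshold:
            label = "sublinear"
        elif d > threshold:
            label = "supralinear"
        else:
            label = "linear"
        rows.append({"roi_id": p.roi_id, "fov_id": p.fov_id,
                     "deviation": d, "label": label})
    return pd.DataFrame(rows)


def median_fractional_deviation(
    pairs: list[SummationPair], floor: float = DEFAULT_EXCLUSION_FLOOR
) -> dict:
    """Per-field medians of fractional deviation and a pooled summary.

    The median is taken over included ROIs within each field of view; the
    pooled summary reports the median of the field medians with the 25th
    and 75th percentiles.
    """
    by_fov: dict[str, list[float]] = {}
    n_excluded = 0
    for p in pairs:
        d = fractional_deviation(p, floor)
        if math.isnan(d):
            n_excluded += 1
            continue
        by_fov.setdefault(p.fov_id, []).append(d)
    if not by_fov:
        raise EmptyFieldError("every ROI was excluded; no field median defined")
    field_medians = {f: float(np.median(v)) for f, v in sorted(by_fov.items())}
    med = np.array(list(field_medians.values()))
    return {
        "field_medians": field_medians,
        "pooled_median": float(np.median(med)),
        "pooled_p25": float(np.percentile(med, 25)),
        "pooled_p75": float(np.percentile(med, 75)),
        "n_excluded_rois": n_excluded,
        "n_rois": sum(len(v) for v in by_fov.values()),
    }


def noise_robustness(
    rm: ResponseMatrix,
    component_a: str,
    component_b: str,
    noise_sds,
    n_repeats: int = 200,
    seed: int = 0,
    floor: float = DEFAULT_EXCLUSION_FLOOR,
) -> pd.DataFrame:
    """Effect of added trial-level Gaussian noise on the fractional-deviation
    distribution.

    For each noise SD and each Monte-Carlo repeat, zero-mean Gaussian noise
    is added to every trial amplitude (all trials, all ROIs) *before* trial
    averaging; fractional deviations are then recomputed.  Returns one row
    per (noise_sd, repeat) with that repeat's median and IQR over included
    ROIs.  Under symmetric noise the median is approximately invariant
    while the distribution broadens with SD.
    """
    noise_sds = np.asarray(noise_sds, dtype=float)
    if np.any(noise_sds < 0):
        raise InvalidArgumentError("noise SDs must be >= 0")
    idx_a = rm.trials_with_stimulus(component_a)
    idx_b = rm.trials_with_stimulus(component_b)
    idx_mix = rm.trials_with_stimulus(component_a, component_b)
    if min(idx_a.size, idx_b.size, idx_mix.size) < 1:
        raise InsufficientTrialsError("missing component or mixture trials")
    a0 = rm.amplitudes[idx_a]
    b0 = rm.amplitudes[idx_b]
    m0 = rm.amplitudes[idx_mix]
    rng = np.random.default_rng(seed)
    rows = []
    for sd in noise_sds:
        for rep in range(n_repeats):
            if sd > 0:
                a = a0 + rng.normal(0, sd, a0.shape)
                b = b0 + rng.normal(0, sd, b0.shape)
                m = m0 + rng.normal(0, sd, m0.shape)
            else:
                a, b, m = a0, b0, m0
            r_lin = a.mean(axis=0) + b.mean(axis=0)
            r_obs = m.mean(axis=0)
            ok = np.abs(r_lin) >= floor
            dev = (r_obs[ok] - r_lin[ok]) / np.abs(r_lin[ok])
            if dev.size == 0:
                continue
            q25, q50, q75 = np.percentile(dev, [25, 50, 75])
            rows.append(
                {
                    "noise_sd": float(sd),
                    "repeat": rep,
                    "median": float(q50),
                    "iqr": float(q75 - q25),
                    "n_included": int(dev.size),
                }
            )
    return pd.DataFrame(rows)


def masking_index(
    rm: ResponseMatrix,
    target: str,
    z_threshold: float = 2.0,
    min_trials: int = 3,
    overlap: str = "ratio",
) -> list[MaskingResult]:
    """Masking index of every background odour against the target pattern.

    From single-odour trials at the glomerular level: trial-averaged target
    responses are z-scored *across glomeruli* within the field; glomeruli
    with z > ``z_threshold`` form the target-responsive set.  For each
    background odour, the per-glomerulus overlap is the clipped ratio
    ``clip(R_bg / R_target, 0, 1)`` (negative responses clip to 0, so the
    maximum overlap per glomerulus is 1); the masking index is the mean
    overlap over the target-responsive set.  ``overlap="min"`` switches to
    the alternative ``min(R_bg, R_target) / R_target`` definition.
    """
    if overlap not in ("ratio", "min"):
        raise InvalidArgumentError(f"unknown overlap definition {overlap!r}")
    singles = sorted({s for s in rm.stimuli if len(s) == 1})
    odours = [s[0] for s in singles]
    if target not in odours:
        raise InsufficientTrialsError(f"no single-odour trials of target {target!r}")
    means = {}
    for o in odours:
        idx = rm.trials_with_stimulus(o)
        if idx.size < min_trials:
            raise InsufficientTrialsError(
                f"odour {o!r} has {idx.size} trials; need >= {min_trials}"
            )
        means[o] = rm.amplitudes[idx].mean(axis=0)
    r_t = means[target]
    z = (r_t - r_t.mean()) / r_t.std(ddof=0)
    responsive = z > z_threshold
    if not responsive.any():
        raise NoReferenceGlomeruliError(
            f"no glomerulus responded to {target!r} with z > {z_threshold}"
        )
    rt = r_t[responsive]
    results = []
    for o in odours:
        if o == target:
            continue
        rb = means[o][responsive]
        if overlap == "ratio":
            ov = np.clip(rb / rt, 0.0, 1.0)
        else:
            ov = np.clip(np.minimum(rb, rt) / rt, 0.0, 1.0)
        results.append(
            MaskingResult(
                odour_id=o,
                masking_index=float(ov.mean()),
                n_target_glomeruli=int(responsive.sum()),
            )
        )
    return results


def pairs_to_frame(pairs: list[SummationPair]) -> pd.DataFrame:
    """Tidy table of summation pairs (one row per ROI)."""
    return pd.DataFrame([p.__dict__ for p in pairs])
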