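"""Normalising-sublinearity model and the in-silico mixture-discriminability test.

The saturating transform is the odd sigmoid

    R* = Rmax * (2 / (1 + exp(-s * R)) - 1)

with saturation ceiling ``Rmax`` (ΔF/F) and slope parameter ``s`` (1/ΔF/F).
Its small-signal gain is ``Rmax * s / 2``, so with the reference parameters
(Rmax = 6, s = 0.2) weak inputs are scaled by 0.6 and the fractional
deviation from linearity tends to −0.4 as R → 0, growing more negative for
larger inputs.

The in-silico experiment: train a zero-intercept linear SVM on single-odour
responses of a field, construct simulated mixture responses as sums of
trial-averaged component responses, add uncorrelated Gaussian noise whose SD
is an affine function of amplitude (``sigma0 + slope * |R|``), optionally
apply the sigmoid, and measure how decoder accuracy on these simulated
mixtures degrades relative to the un-normalised (linear-sum) condition.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    FitFailureError,
    InsufficientTrialsError,
    InvalidArgumentError,
)
from .transients import ResponseMatrix

__all__ = [
    "NormalisationParams",
    "NoiseModel",
    "normalise",
    "fit_normalisation",
    "fit_noise_slope",
    "simulate_mixture_test",
    "sublinearity_experiment",
    "accuracy_ratio",
]


@dataclass(frozen=True)
class NormalisationParams:
    """Sigmoid saturation parameters: ceiling ``rmax`` (ΔF/F) and slope ``s`` (1/ΔF/F)."""

    rmax: float
    s: float

    def __post_init__(self) -> None:
        if not (self.rmax > 0 and self.s > 0):
            raise InvalidArgumentError(
                f"NormalisationParams requires rmax > 0 and s > 0, got {self}"
            )


#: Reference parameters fitted to observed mixture responses of behaving
#: animals (at 2 s after odour onset): Rmax = 6 ΔF/F, s = 0.2 /ΔF/F.
REFERENCE_PARAMS = NormalisationParams(rmax=6.0, s=0.2)


@dataclass(frozen=True)
class NoiseModel:
    """Amplitude-dependent Gaussian noise: SD = sigma0 + slope * |amplitude|."""

    sigma0: float
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.slope < 0:
            raise InvalidArgumentError(
                f"NoiseModel requires sigma0 >= 0 and slope >= 0, got {self}"
            )

    def sd(self, amplitude: np.ndarray) -> np.ndarray:
        return self.sigma0 + self.slope * np.abs(amplitude)


def normalise(R, p: NormalisationParams):
    """Apply the saturating sigmoid R* = Rmax(2/(1+e^{-sR}) − 1).

    Total, odd, strictly increasing, bounded in (−Rmax, Rmax); the
    derivative at 0 is Rmax·s/2.  Accepts scalars or arrays.
    """
    R = np.asarray(R, dtype=float)
    out = p.rmax * (2.0 / (1.0 + np.exp(-p.s * R)) - 1.0)
    return float(out) if out.ndim == 0 else out


def fit_normalisation(
    r_linear: np.ndarray,
    r_observed: np.ndarray,
    p0: NormalisationParams | None = None,
) -> tuple[NormalisationParams, dict]:
    """Least-squares fit of observed mixture amplitudes to the sigmoid of the linear sum.

    Parameters
    ----------
    r_linear, r_observed:
        Per-ROI linear-sum and observed-mixture amplitudes (pooled across
        fields).  At least 10 pairs are required and they should span the
        bend of the curve for the parameters to be identifiable.

    Returns
    -------
    (params, diagnostics) where diagnostics holds ``rmse``, ``n``,
    ``identifiable`` (False when the data carry no curvature, e.g. purely
    linear pairs well inside the linear range, making Rmax degenerate) and
    the relative standard errors of the two parameters.
    """
    x = np.asarray(r_linear, dtype=float)
    y = np.asarray(r_observed, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise InsufficientTrialsError(
            f"need at least 10 (linear sum, observed) pairs, got {x.size}"
        )
    if p0 is None:
        rmax0 = max(1.5 * np.percentile(np.abs(y), 95), 1e-3)
        # small-signal gain rmax*s/2 estimated from a through-origin regression
        gain0 = float(np.dot(x, y) / max(np.dot(x, x), 1e-12))
        s0 = max(2.0 * abs(gain0) / rmax0, 1e-3)
        p0 = NormalisationParams(rmax0, s0)

    def model(r, rmax, s):
        return rmax * (2.0 / (1.0 + np.exp(-s * r)) - 1.0)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = optimize.curve_fit(
                model,
                x,
                y,
                p0=[p0.rmax, p0.s],
                bounds=([1e-6, 1e-6], [np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitFailureError(f"sigmoid fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.inf)
    rel_err = perr / np.abs(popt)
    diagnostics = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "n": int(x.size),
        "rel_err_rmax": float(rel_err[0]),
        "rel_err_s": float(rel_err[1]),
        # no usable curvature -> Rmax and s trade off; flag rather than trust
        "identifiable": bool(np.all(rel_err < 1.0)),
    }
    return NormalisationParams(float(popt[0]), float(popt[1])), diagnostics


def fit_noise_slope(rm: ResponseMatrix, sigma0: float) -> NoiseModel:
    """Estimate how trial-to-trial SD scales with response amplitude.

    For each ROI and each repeated stimulus, the across-trial SD is
    regressed (OLS) on the absolute trial-mean amplitude; the slope is the
    amplitude-scaling of the noise.  ``sigma0`` (the baseline SD: 0.2 for
    anaesthetised data, 2 for the awake, behaving case) is supplied by the
    state preset, not estimated.  A negative fitted slope is clipped to 0
    with a warning (an SD cannot decrease below baseline in the model).
    """
    if rm.n_rois < 5:
        raise InsufficientTrialsError(
            f"need at least 5 ROIs to regress SD on amplitude, got {rm.n_rois}"
        )
    means, sds = [], []
    for stim in sorted(set(rm.stimuli)):
        idx = rm.trials_with_stimulus(*stim)
        if idx.size < 3:
            continue
        sub = rm.amplitudes[idx]
        means.append(np.abs(sub.mean(axis=0)))
        sds.append(sub.std(axis=0, ddof=1))
    if not means:
        raise InsufficientTrialsError(
            "no stimulus has >= 3 trials; cannot estimate trial-to-trial SD"
        )
    x = np.concatenate(means)
    y = np.concatenate(sds)
    slope = float(stats.linregress(x, y).slope)
    if slope < 0:
        warnings.warn(
            f"fitted noise slope {slope:.3f} < 0; clipping to 0", stacklevel=2
        )
        slope = 0.0
    return NoiseModel(sigma0=float(sigma0), slope=slope)


def _single_odour_averages(
    rm: ResponseMatrix, target: str
) -> tuple[dict[str, np.ndarray], list[str]]:
    averages: dict[str, np.ndarray] = {}
    for stim in sorted(set(rm.stimuli)):
        if len(stim) != 1:
            continue
        idx = rm.trials_with_stimulus(*stim)
        averages[stim[0]] = rm.amplitudes[idx].mean(axis=0)
    if target not in averages:
        raise InsufficientTrialsError(f"no single-odour trials of target {target!r}")
    odours = sorted(averages)
    return averages, odours


def simulate_mixture_test(
    rm: ResponseMatrix,
    decoder,
    noise: NoiseModel,
    target: str,
    params: NormalisationParams | None = None,
    n_reps: int = 20,
    rng: np.random.Generator | None = None,
) -> float:
    """Accuracy of a single-odour-trained decoder on simulated mixtures.

    For every unordered pair of distinct odours in the session's single-odour
    set, component responses are averaged across trials and summed; per-ROI
    uncorrelated Gaussian noise with SD = sigma0 + slope·|amplitude| is drawn
    fresh for each of ``n_reps`` repetitions; the sum is optionally passed
    through the saturating sigmoid (``params``); the decoder classifies the
    result as target-present or not.  Returns the balanced accuracy (mean of
    the target-present and target-absent correct rates) over pairs × reps.

    With ``params=None`` and a zero-noise model this is exactly the decoder's
    accuracy on noiseless linear sums.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_reps < 1:
        raise InvalidArgumentError("n_reps must be >= 1")
    averages, odours = _single_odour_averages(rm, target)
    if len(odours) < 3:
        raise InsufficientTrialsError("need at least 3 single odours to form mixtures")
    sums, labels = [], []
    for a, b in itertools.combinations(odours, 2):
        sums.append(averages[a] + averages[b])
        labels.append(target in (a, b))
    S = np.stack(sums)  # n_pairs x n_rois
    y = np.asarray(labels)
    correct_pos = correct_neg = 0
    n_pos = int(y.sum()) * n_reps
    n_neg = int((~y).sum()) * n_reps
    for _ in range(n_reps):
        X = S + rng.normal(0.0, noise.sd(S))
        if params is not None:
            X = normalise(X, params)
        pred = decoder.predict(X)
        correct_pos += int(np.sum(pred[y] == True))  # noqa: E712
        correct_neg += int(np.sum(pred[~y] == False))  # noqa: E712
    return 0.5 * (correct_pos / n_pos + correct_neg / n_neg)


def sublinearity_experiment(
    rms_per_time: list[tuple[float, ResponseMatrix]],
    noise: NoiseModel,
    target: str,
    params: NormalisationParams = REFERENCE_PARAMS,
    n_reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full linear-sum vs normalised simulation over a time course.

    At each time point a zero-intercept linear SVM is trained on that
    window's single-odour responses (target vs other singles); simulated
    mixtures are then tested in two conditions: ``linear`` (sum + noise) and
    ``sublinear`` (sum + noise, then sigmoid).  The same fitted/reference
    parameters are applied at every time point.

    Returns a tidy DataFrame (time, condition, accuracy, fov_id).
    """
    from .decoding import train_linear_decoder  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    rows = []
    for t, rm in rms_per_time:
        singles = rm.subset(np.flatnonzero(rm.labels["n_components"] == 1))
        decoder = train_linear_decoder(singles)
        for cond, p in (("linear", None), ("sublinear", params)):
            acc = simulate_mixture_test(
                rm,
                decoder,
                noise,
                target,
                params=p,
                n_reps=n_reps,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            rows.append(
                {"time": t, "condition": cond, "accuracy": acc, "fov_id": rm.fov_id}
            )
    return pd.DataFrame(rows)


def accuracy_ratio(
    experiments: list[pd.DataFrame],
    early_phase: tuple[float, float] = (0.0, 1.5),
    late_phase: tuple[float, float] = (1.5, 3.0),
) -> dict:
    """Sublinear accuracy as a fraction of the linear-sum baseline, per field.

    ``experiments`` is one tidy table per field (from
    :func:`sublinearity_experiment`).  For each field the time course of
    ratios is computed elementwise (time bins with zero baseline accuracy are
    excluded with a warning), then averaged over the early (0–1.5 s] and late
    (1.5–3 s] phases.  Returns per-field phase means, the ratio time course,
    and a paired t-test of sublinear vs linear phase-mean accuracies across
    fields (one per phase).
    """
    per_field = []
    ratio_rows = []
    for df in experiments:
        wide = df.pivot_table(index="time", columns="condition", values="accuracy")
        ok = wide["linear"] > 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} time bin(s) with zero baseline accuracy excluded",
                stacklevel=2,
            )
        ratio = (wide.loc[ok, "sublinear"] / wide.loc[ok, "linear"]).rename("ratio")
        fov = df["fov_id"].iloc[0]
        for t, r in ratio.items():
            ratio_rows.append({"fov_id": fov, "time": t, "ratio": r})
        rec = {"fov_id": fov}
        for name, (lo, hi) in (("early", early_phase), ("late", late_phase)):
            in_phase = (ratio.index > lo) & (ratio.index <= hi)
            rec[f"{name}_ratio"] = float(ratio[in_phase].mean())
            rec[f"{name}_linear"] = float(wide.loc[ok, "linear"][in_phase].mean())
            rec[f"{name}_sublinear"] = float(wide.loc[ok, "sublinear"][in_phase].mean())
        per_field.append(rec)
    fields = pd.DataFrame(per_field)
    tests = {}
    for name in ("early", "late"):
        t, p = stats.ttest_rel(fields[f"{name}_sublinear"], fields[f"{name}_linear"])
        tests[name] = {"t": float(t), "p": float(p)}
    return {
        "per_field": fields,
        "ratio_timecourse": pd.DataFrame(ratio_rows),
        "paired_ttest": tests,
    }


def compare_state_ratios(
    ratios_a: np.ndarray, ratios_b: np.ndarray
) -> dict:
    """Welch two-sample comparison of phase-mean accuracy ratios between states."""
    t, p = stats.ttest_ind(ratios_a, ratios_b, equal_var=False)
    return {
        "mean_a": float(np.mean(ratios_a)),
        "mean_b": float(np.mean(ratios_b)),
        "t": float(t),
        "p": float(p),
    }
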