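"""Session readers/writers and tabular import/export.

A session directory holds one ``.npy`` array per trial (ROI × frame) plus a
``manifest.csv`` with one row per trial (file name, frame rate, onset frame,
stimulus components joined by '+', state, field id, reward flag, ΔF/F flag).
Deposited-style summation data — a two-column table of (linear sum,
observed) amplitude pairs per field — loads into :class:`SummationPair`
lists.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SessionIOError
from .summation import SummationPair
from .transients import TrialRecording

__all__ = [
    "save_session",
    "load_session",
    "load_summation_pairs",
    "save_json",
]

MANIFEST_COLUMNS = [
    "trial",
    "file",
    "frame_rate_hz",
    "onset_frame",
    "stimulus",
    "state",
    "fov_id",
    "rewarded",
    "is_dff",
]


def save_session(trials: Sequence[TrialRecording], path: str | Path) -> Path:
    """Write a session to a directory of per-trial arrays plus a CSV manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(trials):
        fname = f"trial{i:04d}.npy"
        np.save(path / fname, t.fluorescence)
        rows.append(
            {
                "trial": i,
                "file": fname,
                "frame_rate_hz": t.frame_rate_hz,
                "onset_frame": t.onset_frame,
                "stimulus": "+".join(t.stimulus),
                "state": t.state,
                "fov_id": t.fov_id,
                "rewarded": "" if t.rewarded is None else str(bool(t.rewarded)),
                "is_dff": str(bool(t.is_dff)),
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        path / "manifest.csv", index=False
    )
    return path


def load_session(path: str | Path) -> list[TrialRecording]:
    """Load a session directory written by :func:`save_session`.

    Validates manifest/array consistency (files present, required metadata,
    consistent frame counts) and raises :class:`SessionIOError` naming the
    offending trial otherwise.
    """
    path = Path(path)
    manifest_path = path / "manifest.csv"
    if not manifest_path.exists():
        raise SessionIOError(f"no manifest.csv in {path}")
    manifest = pd.read_csv(manifest_path, dtype={"rewarded": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SessionIOError(f"manifest missing column(s) {missing}")
    trials = []
    for _, row in manifest.iterrows():
        f = path / str(row["file"])
        if not f.exists():
            raise SessionIOError(f"trial {row['trial']}: array file {f.name} missing")
        try:
            onset = int(row["onset_frame"])
        except (TypeError, ValueError) as exc:
            raise SessionIOError(
                f"trial {row['trial']}: invalid onset_frame {row['onset_frame']!r}"
            ) from exc
        arr = np.load(f)
        rewarded_raw = str(row["rewarded"])
        rewarded = None if rewarded_raw == "" else rewarded_raw == "True"
        trials.append(
            TrialRecording(
                fluorescence=arr,
                frame_rate_hz=float(row["frame_rate_hz"]),
                onset_frame=onset,
                stimulus=tuple(str(row["stimulus"]).split("+")),
                state=str(row["state"]),
                fov_id=str(row["fov_id"]),
                rewarded=rewarded,
                is_dff=str(row["is_dff"]) == "True",
            )
        )
    n_frames = {t.n_frames for t in trials}
    if len(n_frames) > 1:
        raise SessionIOError(f"inconsistent frame counts across trials: {n_frames}")
    return trials


def load_summation_pairs(
    path: str | Path,
    linear_col: str = "linear_sum",
    observed_col: str = "observed",
    fov_col: str = "fov_id",
) -> list[SummationPair]:
    """Load a deposited-style (linear sum, observed) amplitude table.

    The table is one row per ROI with the linear-sum and observed mixture
    amplitude over the 300–1000 ms post-onset window; an optional field
    column groups ROIs by field of view (a single unnamed field otherwise).
    Trial dispersion is not part of this format, so SEMs load as 0 and the
    joint-SEM deviation is not available from it.
    """
    df = pd.read_csv(path)
    for col in (linear_col, observed_col):
        if col not in df.columns:
            raise SessionIOError(f"{path}: missing column {col!r}")
    fovs = df[fov_col] if fov_col in df.columns else pd.Series(["fov0"] * len(df))
    return [
        SummationPair(
            roi_id=i,
            r_observed=float(df[observed_col].iloc[i]),
            r_linear=float(df[linear_col].iloc[i]),
            sem_observed=0.0,
            sem_linear=0.0,
            n_trials_mixture=0,
            n_trials_components=0,
            fov_id=str(fovs.iloc[i]),
        )
        for i in range(len(df))
    ]


def save_json(obj: dict, path: str | Path) -> Path:
    """Write a JSON summary, converting numpy scalars/arrays along the way."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
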