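"""Per-trial RMS features of the CSD/AVREC and within-session z-scoring.

Features are root-mean-square values of the AVREC trace and of the mean CSD
trace within each laminar band, measured in half-open 500-ms windows locked
to CS onsets (and a 500-1000 ms late variant), over the whole trace, and in
choice-locked windows anchored at the CS presentation preceding the
behavioral response.  Single-trial values are z-scored across trials within
animal x session (and window/signal), matching the normalization used
before all statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import TrialRecord
from .signal import (
    AVRECTrace,
    CSDParams,
    CSDProfile,
    LaminarRecording,
    LayerMap,
    LAYERS,
    avrec,
    compute_csd,
    interpolate_bad_channels,
    reject_artifacts,
    smooth_channels,
)

WINDOW_KINDS = ("cs_onset_500ms", "late_500_1000ms", "whole_trace", "choice_locked")
SIGNALS = ("AVREC",) + LAYERS
RMS_WINDOW_S = 0.5
MAX_CS_INDEX = 4


def window_rms(trace: np.ndarray, fs: float, t0: float, start: float,
               duration: float) -> float:
    """RMS over the half-open window [start, start + duration).

    ``t0`` is the time of the trace's first sample; samples are selected by
    their start time.
    """
    if duration <= 0:
        raise ValueError("window duration must be positive")
    t = t0 + np.arange(len(trace)) / fs
    sel = (t >= start) & (t < start + duration)
    if not sel.any():
        raise ValueError(f"window [{start}, {start + duration}) selects no samples")
    x = np.asarray(trace, dtype=float)[sel]
    return float(np.sqrt(np.mean(x * x)))


def layer_trace(csd: CSDProfile, band: tuple[int, int]) -> np.ndarray:
    """Signed per-sample mean of the CSD across one laminar band's channels."""
    lo, hi = band
    if lo < 0 or hi >= csd.n_channels or lo > hi:
        raise ValueError(f"band ({lo}, {hi}) outside CSD channels")
    return csd.values[lo : hi + 1].mean(axis=0)


def choice_locked_windows(trial: TrialRecord, n_back: int = 3,
                          rms_window: float = RMS_WINDOW_S) -> dict:
    """Anchor CS onsets for the response-locked analysis.

    The anchor (back index 0) is the last CS onset strictly before the
    crossing for responded trials (hit/FA), the 4th CS onset for misses, and
    the last CS onset whose window fits the NoGo trial for correct
    rejections.  Back indices k = 1..n_back step one CS earlier; keys with no
    CS available are absent.  Returns {} for trials whose crossing precedes
    the first CS (flagged inconsistent upstream).
    """
    onsets = np.asarray(trial.cs_onsets_s, dtype=float)
    if trial.outcome in ("hit", "FA"):
        before = np.flatnonzero(onsets < trial.crossing_time_s)
        if before.size == 0:
            return {}
        anchor = int(before[-1])
    elif trial.outcome == "miss":
        anchor = min(MAX_CS_INDEX, onsets.size) - 1
    else:  # CorrRej
        fits = np.flatnonzero(onsets + rms_window <= trial.window_length_s)
        anchor = int(fits[-1])
    out = {}
    for k in range(n_back + 1):
        idx = anchor - k
        if idx >= 0:
            out[k] = float(onsets[idx])
    return out


def znorm(df: pd.DataFrame, value_col: str, group_cols: list[str],
          out_col: str | None = None) -> pd.DataFrame:
    """z-score ``value_col`` within groups (n-1 SD); degenerate groups -> NaN.

    Groups with fewer than two values or zero spread are flagged missing and
    a warning is emitted rather than producing infinities.
    """
    out_col = out_col or value_col + "_z"
    df = df.copy()
    g = df.groupby(group_cols, sort=False, dropna=False)[value_col]
    mean = g.transform("mean")
    sd = g.transform("std")  # ddof=1
    bad = (sd == 0) | sd.isna() | (g.transform("count") < 2)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} values in degenerate z-norm groups set to NaN",
            stacklevel=2,
        )
    z = (df[value_col] - mean) / sd
    z[bad] = np.nan
    df[out_col] = z
    return df


@dataclass
class PreprocessParams:
    """Knobs of the per-trial preprocessing chain."""

    bad_channels: tuple = ()
    artifact_sd_threshold: float = 10.0
    csd: CSDParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.csd is None:
            self.csd = CSDParams()


def preprocess_trial(rec: LaminarRecording, trial: TrialRecord,
                     params: PreprocessParams):
    """interpolate -> artifact mask/flag -> smooth -> CSD -> AVREC."""
    rec = interpolate_bad_channels(rec, set(params.bad_channels))
    us_onset = None
    if trial.outcome == "miss":
        us_onset = trial.window_length_s  # shock at window end clips the signal
    rec, report = reject_artifacts(rec, params.artifact_sd_threshold, us_onset)
    rec = smooth_channels(rec, params.csd.smoothing_channels)
    csd = compute_csd(rec, params.csd)
    return csd, avrec(csd), report


def trial_feature_rows(csd: CSDProfile, av: AVRECTrace, trial: TrialRecord,
                       layer_map: LayerMap, n_back: int = 3) -> list[dict]:
    """All RMS feature rows for one preprocessed trial."""
    traces = {"AVREC": av.values}
    for layer in LAYERS:
        traces[layer] = layer_trace(csd, layer_map.bands[layer])
    fs, t0 = csd.fs, csd.t0
    end = csd.times[-1] + 1.0 / fs
    crossing = trial.crossing_time_s
    stop = min(crossing, trial.window_length_s) if crossing is not None else trial.window_length_s

    windows = []  # (kind, cs_index, back_k, start, duration)
    onsets = np.asarray(trial.cs_onsets_s, dtype=float)
    for k, onset in enumerate(onsets[:MAX_CS_INDEX], start=1):
        if crossing is not None and onset >= crossing:
            break  # CS not presented; nothing to measure
        if onset + RMS_WINDOW_S <= end:
            windows.append(("cs_onset_500ms", k, None, onset, RMS_WINDOW_S))
        if onset + 1.0 <= end:
            windows.append(("late_500_1000ms", k, None, onset + RMS_WINDOW_S, RMS_WINDOW_S))
    if stop > 0:
        windows.append(("whole_trace", None, None, 0.0, min(stop, end)))
    for back_k, onset in choice_locked_windows(trial, n_back).items():
        if onset + RMS_WINDOW_S <= end:
            windows.append(("choice_locked", None, back_k, onset, RMS_WINDOW_S))

    rows = []
    for kind, cs_index, back_k, start, dur in windows:
        for signal, trace in traces.items():
            rows.append({
                "subject": trial.subject, "session": trial.session,
                "phase": trial.phase, "trial_id": trial.trial_id,
                "outcome": trial.outcome, "cs_frequency_hz": trial.cs_frequency_hz,
                "contingency": trial.contingency, "window_kind": kind,
                "cs_index": cs_index, "back_k": back_k, "layer": signal,
                "rms_raw": window_rms(trace, fs, t0, start, dur),
            })
    return rows


def build_feature_table(
    trials,
    layer_map: LayerMap,
    params: PreprocessParams | None = None,
    n_back: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the tidy feature table from (recording, trial) pairs.

    ``trials`` is any iterable of (LaminarRecording, TrialRecord); rejected
    trials contribute no feature rows.  Returns (features, rejection_log);
    features carry both raw and within-animal x session z-scored RMS.
    """
    params = params or PreprocessParams()
    rows, rejections = [], []
    n_total = 0
    for rec, trial in trials:
        n_total += 1
        csd, av, report = preprocess_trial(rec, trial, params)
        if report.rejected:
            rejections.append({"trial_id": trial.trial_id, "reason": report.reason})
            continue
        rows.extend(trial_feature_rows(csd, av, trial, layer_map, n_back))
    if not rows:
        raise ValueError("no feature rows produced (all trials rejected or empty)")
    df = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse cells are expected at high back_k
        df = znorm(
            df, "rms_raw",
            ["subject", "session", "window_kind", "cs_index", "back_k", "layer"],
            out_col="rms_z",
        )
    rej = pd.DataFrame(rejections, columns=["trial_id", "reason"])
    return df, rej
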