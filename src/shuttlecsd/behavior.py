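"""Trial-outcome bookkeeping and signal-detection performance measures.

In the shuttle-box task a Go trial requires a compartment change within the
6-s observation window (hit; staying is a miss), while a NoGo trial requires
staying for the full 12-15 s window (correct rejection; crossing is a false
alarm).  Session sensitivity is summarized as

    d' = Z(hit rate) - Z(relative intertrial-shuttle rate)

with Z the standard-normal quantile function; rates are clipped to
[1/(2N), 1 - 1/(2N)] so d' stays finite at 0/1 rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

OUTCOMES = ("hit", "miss", "FA", "CorrRej")

#: trial-table column names used across the package
TRIAL_COLUMNS = [
    "subject", "session", "phase", "trial_id", "cs_frequency_hz",
    "contingency", "window_length_s", "crossing_time_s", "outcome",
    "intertrial_shuttle",
]


@dataclass
class TrialRecord:
    """Per-trial behavioral metadata."""

    subject: str
    session: int
    phase: str                 # "detection" | "discrimination"
    trial_id: str
    cs_frequency_hz: float     # 1000 or 4000
    contingency: str           # "Go" | "NoGo"
    window_length_s: float
    cs_onsets_s: tuple         # CS onset times, trial-relative seconds
    crossing_time_s: float | None = None
    outcome: str | None = None
    intertrial_shuttle: int = 0

    def __post_init__(self) -> None:
        if self.contingency not in ("Go", "NoGo"):
            raise ValueError(f"unknown contingency {self.contingency!r}")
        if self.phase == "detection" and self.contingency != "Go":
            raise ValueError("detection phase has Go contingency only")


def classify_outcome(
    contingency: str,
    crossing_time: float | None,
    window_length: float,
    go_window: float = 6.0,
) -> str:
    """Map (contingency, crossing) to hit / miss / FA / CorrRej."""
    if contingency not in ("Go", "NoGo"):
        raise ValueError(f"unknown contingency {contingency!r}")
    if crossing_time is not None:
        if crossing_time < 0 or crossing_time > window_length:
            raise ValueError(
                f"crossing time {crossing_time} outside trial window "
                f"[0, {window_length}]"
            )
    if contingency == "Go":
        if crossing_time is not None and crossing_time <= go_window:
            return "hit"
        return "miss"
    if crossing_time is not None:
        return "FA"
    return "CorrRej"


def clip_rate(rate: float, n_trials: int) -> float:
    """Log-linear 1/(2N) correction keeping quantiles finite at 0/1 rates."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo = 1.0 / (2.0 * n_trials)
    return float(np.clip(rate, lo, 1.0 - lo))


def dprime(hit_rate: float, its_rate: float, n_trials: int) -> float:
    """Sensitivity d' = Z(hits) - Z(ITS) with 1/(2N)-clipped rates."""
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= its_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    h = clip_rate(hit_rate, n_trials)
    f = clip_rate(its_rate, n_trials)
    return float(norm.ppf(h) - norm.ppf(f))


def criterion_session(
    dprime_by_session, threshold: float = 1.0, run: int = 3
) -> int | None:
    """First session (1-based) completing `run` consecutive d' > threshold."""
    values = list(dprime_by_session)
    if not values:
        raise ValueError("empty d' sequence")
    streak = 0
    for i, d in enumerate(values, start=1):
        streak = streak + 1 if d > threshold else 0
        if streak >= run:
            return i
    return None


def session_dprime(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-session d' from Go hit rates and relative intertrial shuttles.

    The ITS rate is the fraction of trials whose intertrial interval
    contained at least one shuttle; other normalizations of the "relative
    intertrial shuttles" can be obtained by pre-aggregating differently.
    """
    rows = []
    for (subject, session), g in trials.groupby(["subject", "session"], sort=True):
        go = g[g["contingency"] == "Go"]
        if len(go) == 0:
            continue
        hit_rate = float((go["outcome"] == "hit").mean())
        its_rate = float((g["intertrial_shuttle"] > 0).mean())
        n = len(go)
        rows.append({
            "subject": subject, "session": session,
            "hit_rate": hit_rate, "its_rate": its_rate,
            "n_go_trials": n, "dprime": dprime(hit_rate, its_rate, n),
        })
    return pd.DataFrame(rows)


def cr_rates_by_session(trials: pd.DataFrame) -> pd.DataFrame:
    """Conditioned-response rates per session and CS frequency.

    Go trials contribute hit rates, NoGo trials FA rates.  A session without
    trials of a class yields no row (absent, never zero).
    """
    rows = []
    keys = ["subject", "session", "cs_frequency_hz", "contingency"]
    for (subject, session, freq, cont), g in trials.groupby(keys, sort=True):
        responded = "hit" if cont == "Go" else "FA"
        rows.append({
            "subject": subject, "session": session,
            "cs_frequency_hz": freq, "contingency": cont,
            "cr_rate": float((g["outcome"] == responded).mean()),
            "n_trials": len(g),
        })
    return pd.DataFrame(rows)


def reaction_time_histogram(
    trials: pd.DataFrame, bin_width: float, t_max: float | None = None
) -> pd.DataFrame:
    """Histogram of crossing times (trial-relative) over responding trials."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    rt = trials["crossing_time_s"].dropna().to_numpy(dtype=float)
    if t_max is None:
        t_max = float(trials["window_length_s"].max())
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, edges = np.histogram(rt, bins=edges)
    return pd.DataFrame({
        "bin_left_s": edges[:-1], "bin_right_s": edges[1:], "count": counts,
    })
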