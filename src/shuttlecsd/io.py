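"""On-disk cohort container: HDF5 laminar recordings + CSV trial table.

Layout of ``recordings.h5``: one group per trial id under ``/trials``, each
holding a float dataset ``lfp`` (channels x samples) with attributes
``fs_hz``, ``spacing_um``, ``t0_s`` and ``channel_order`` ("superficial
first").  The behavioral trial table travels as ``trials.csv`` and the
generator's ground truth as ``ground_truth.json``; bad-channel/artifact
annotations, when present, as ``annotations.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import TrialRecord
from .signal import LaminarRecording

RECORDINGS = "recordings.h5"
TRIALS = "trials.csv"
TRUTH = "ground_truth.json"


class ContainerError(RuntimeError):
    """Raised when a cohort container is missing pieces or corrupt."""


def write_cohort(cfg, outdir) -> None:
    from .synthetic import GroundTruth, iter_cohort_trials, trial_table

    outdir = Path(outdir)
    trials = []
    with h5py.File(outdir / RECORDINGS, "w") as h5:
        h5.attrs["format"] = "shuttlecsd-laminar-v1"
        grp = h5.create_group("trials")
        for rec, trial in iter_cohort_trials(cfg):
            g = grp.create_group(trial.trial_id)
            d = g.create_dataset("lfp", data=rec.data.astype(np.float32),
                                 compression="gzip", compression_opts=4,
                                 track_times=False)
            d.attrs["fs_hz"] = rec.fs
            d.attrs["spacing_um"] = rec.spacing_um
            d.attrs["t0_s"] = rec.t0
            d.attrs["channel_order"] = "superficial first"
            trials.append(trial)
    trial_table(trials).to_csv(outdir / TRIALS, index=False)
    GroundTruth.from_config(cfg).to_json(outdir / TRUTH)


def read_trial_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ContainerError(f"trial table not found: {path}")
    df = pd.read_csv(path)
    required = {"subject", "session", "phase", "trial_id", "contingency",
                "window_length_s", "outcome"}
    missing = required - set(df.columns)
    if missing:
        raise ContainerError(f"trial table {path} missing columns {sorted(missing)}")
    return df


def _row_to_record(row) -> TrialRecord:
    onsets = tuple(float(x) for x in str(row["cs_onsets_s"]).split(";")) \
        if "cs_onsets_s" in row and isinstance(row["cs_onsets_s"], str) else ()
    crossing = row.get("crossing_time_s")
    if crossing is not None and (crossing != crossing):  # NaN
        crossing = None
    return TrialRecord(
        subject=row["subject"], session=int(row["session"]), phase=row["phase"],
        trial_id=row["trial_id"], cs_frequency_hz=float(row["cs_frequency_hz"]),
        contingency=row["contingency"], window_length_s=float(row["window_length_s"]),
        cs_onsets_s=onsets, crossing_time_s=crossing, outcome=row["outcome"],
        intertrial_shuttle=int(row.get("intertrial_shuttle", 0)),
    )


def iter_cohort(indir):
    """Yield (LaminarRecording, TrialRecord) from an on-disk container."""
    indir = Path(indir)
    table = read_trial_table(indir / TRIALS)
    h5path = indir / RECORDINGS
    if not h5path.exists():
        raise ContainerError(f"recording container not found: {h5path}")
    try:
        h5 = h5py.File(h5path, "r")
    except OSError as err:
        raise ContainerError(f"cannot open container {h5path}: {err}") from err
    with h5:
        for _, row in table.iterrows():
            tid = row["trial_id"]
            if f"trials/{tid}" not in h5:
                raise ContainerError(f"{h5path}: trial {tid!r} missing from container")
            d = h5[f"trials/{tid}/lfp"]
            rec = LaminarRecording(
                np.asarray(d, dtype=float), fs=float(d.attrs["fs_hz"]),
                spacing_um=float(d.attrs["spacing_um"]), t0=float(d.attrs["t0_s"]),
            )
            yield rec, _row_to_record(row)


def read_ground_truth(indir) -> dict:
    path = Path(indir) / TRUTH
    if not path.exists():
        raise ContainerError(f"ground truth not found: {path}")
    return json.loads(path.read_text())
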