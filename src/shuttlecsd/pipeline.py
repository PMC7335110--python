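"""End-to-end orchestration: simulate -> preprocess/CSD -> features -> fit.

Two execution styles share the same stages: the streaming runner
(`run_pipeline`) regenerates trials lazily from a cohort config so a full
cohort never touches disk, while the stage-wise CLI operates on the on-disk
container for externally supplied data.  Every run writes a JSON manifest
with the config, seed, package version and SHA-256 of each output table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import cr_rates_by_session, session_dprime
from .features import PreprocessParams, build_feature_table
from .inference import (
    GLMMSpec,
    effect_size_from_fit,
    fit_glmm,
    layer_predictability_map,
    timeresolved_effects,
)
from .io import iter_cohort
from .signal import CSDParams, LayerMap, LAYERS
from .synthetic import CohortConfig, iter_cohort_trials, trial_table

log = logging.getLogger("shuttlecsd")

#: the standard model battery mirroring the published analysis structure
DEFAULT_MODELS = (
    # name, phase, class column, (class0, class1), window kind, back_k
    ("frequency_detection", "detection", "cs_frequency_hz", (4000.0, 1000.0),
     "whole_trace", None),
    ("frequency_discrimination", "discrimination", "cs_frequency_hz",
     (4000.0, 1000.0), "whole_trace", None),
    ("choice_go_detection", "detection", "outcome", ("miss", "hit"),
     "choice_locked", 0),
    ("choice_go_discrimination", "discrimination", "outcome", ("miss", "hit"),
     "choice_locked", 0),
    ("choice_nogo_discrimination", "discrimination", "outcome",
     ("CorrRej", "FA"), "choice_locked", 0),
    ("correct_choices", "discrimination", "outcome", ("CorrRej", "hit"),
     "choice_locked", 0),
    ("incorrect_choices", "discrimination", "outcome", ("miss", "FA"),
     "choice_locked", 0),
)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    outdir: str = "run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    csd: CSDParams = field(default_factory=CSDParams)
    artifact_sd_threshold: float = 10.0
    bad_channels: tuple = ()
    random_slope: bool = True
    use_ground_truth_layer_map: bool = True
    n_back: int = 3
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{
            **raw.get("cohort", {}),
            **({"nogo_window_s": tuple(raw["cohort"]["nogo_window_s"])}
               if "nogo_window_s" in raw.get("cohort", {}) else {}),
        })
        csd = CSDParams(**raw.get("csd", {}))
        keys = {k: v for k, v in raw.items() if k not in ("cohort", "csd")}
        if "bad_channels" in keys:
            keys["bad_channels"] = tuple(keys["bad_channels"])
        return cls(cohort=cohort, csd=csd, **keys)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["nogo_window_s"] = list(d["cohort"]["nogo_window_s"])
        d["cohort"]["phases"] = list(d["cohort"]["phases"])
        d["bad_channels"] = list(d["bad_channels"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def fit_model_battery(features: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Fit the AVREC + per-layer GLMMs for every standard comparison."""
    rows = []
    for name, phase, class_col, classes, window_kind, back_k in DEFAULT_MODELS:
        spec = GLMMSpec(classes=classes, class_col=class_col,
                        random_slope=cfg.random_slope)
        for layer in ("AVREC",) + LAYERS:
            sel = (features["phase"] == phase) \
                & (features["layer"] == layer) \
                & (features["window_kind"] == window_kind)
            if back_k is not None:
                sel &= features["back_k"] == back_k
            sub = features[sel]
            counts = sub[sub[class_col].isin(classes)][class_col].value_counts()
            row = {"model": name, "phase": phase, "layer": layer,
                   "window_kind": window_kind, "back_k": back_k,
                   "class0": classes[0], "class1": classes[1]}
            if len(counts) == 2 and counts.min() >= 5:
                try:
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        es = effect_size_from_fit(fit_glmm(sub, spec))
                    row.update(beta=es.beta, se=es.beta_se, p=es.p,
                               r2m=es.r2m, r2c=es.r2c, band=es.band,
                               p_category=es.p_category, n_obs=es.n_obs,
                               n_groups=es.n_groups)
                except (ValueError, RuntimeError, np.linalg.LinAlgError) as err:
                    row.update(error=str(err))
            else:
                row.update(error="insufficient trials per class")
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, trials=None) -> dict:
    """Run simulate -> preprocess -> csd -> features -> fit, streaming.

    ``trials`` may supply an existing iterable of (recording, trial record)
    pairs (e.g. from :func:`shuttlecsd.io.iter_cohort`); by default trials
    are generated lazily from ``cfg.cohort``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))
    stages = []

    if trials is None:
        log.info("stage simulate: streaming cohort seed=%d", cfg.cohort.seed)
        trials = iter_cohort_trials(cfg.cohort)
        stages.append("simulate")

    layer_map = cfg.cohort.layer_map() if cfg.use_ground_truth_layer_map else None
    if layer_map is None:
        raise ValueError("automatic layer assignment requires an averaged CSD; "
                         "enable use_ground_truth_layer_map or supply a map")
    params = PreprocessParams(bad_channels=cfg.bad_channels,
                              artifact_sd_threshold=cfg.artifact_sd_threshold,
                              csd=cfg.csd)
    collected = []

    def _tee():
        for rec, trial in trials:
            collected.append(trial)
            yield rec, trial

    features, rejections = build_feature_table(_tee(), layer_map, params,
                                               n_back=cfg.n_back)
    stages.extend(["preprocess", "csd", "features"])
    log.info("features: %d rows from %d trials (%d rejected)",
             len(features), len(collected), len(rejections))

    tbl = trial_table(collected)
    behavior = session_dprime(tbl)
    cr = cr_rates_by_session(tbl)
    models = fit_model_battery(features, cfg)
    stages.append("fit")

    outputs = {
        "trials.csv": tbl, "features.csv": features,
        "rejections.csv": rejections, "behavior_dprime.csv": behavior,
        "cr_rates.csv": cr, "models.csv": models,
    }
    for name, df in outputs.items():
        _write_csv(df, outdir / name)
    manifest = {
        "package": "shuttlecsd", "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.cohort.seed, "config": cfg.to_dict(), "stages": stages,
        "outputs": {n: _sha256(outdir / n) for n in outputs},
        "n_trials": len(collected), "n_rejected": len(rejections),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return {"manifest": manifest, "features": features, "models": models,
            "behavior": behavior, "trials": tbl}


def report(outdir) -> str:
    """Render a text summary of a completed run's result tables."""
    outdir = Path(outdir)
    models = pd.read_csv(outdir / "models.csv")
    behavior = pd.read_csv(outdir / "behavior_dprime.csv")
    lines = ["shuttlecsd run report", "=" * 60]
    lines.append(f"Sessions analyzed: {len(behavior)}; "
                 f"mean d' = {behavior['dprime'].mean():.2f}")
    for model, g in models.groupby("model", sort=False):
        lines.append(f"\n[{model}]")
        for _, r in g.iterrows():
            if isinstance(r.get("error"), str):
                lines.append(f"  {r['layer']:<8} -- {r['error']}")
            else:
                lines.append(
                    f"  {r['layer']:<8} beta={r['beta']:+.3f}  R2m={r['r2m']:.3f} "
                    f"({r['band']}, p {r['p_category']})  R2c={r['r2c']:.3f}"
                )
    return "\n".join(lines)


FIXTURE_SIZES = {
    # name: (subjects, sessions per phase, trials per session)
    "tiny": (2, 1, 20),
    "small": (8, 2, 60),
}


def fixture_config(size: str = "tiny", seed: int = 0, **overrides) -> RunConfig:
    """Cohort-scale presets: tiny (seconds) and small (~ the study's n)."""
    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}")
    n_subj, n_sess, n_trials = FIXTURE_SIZES[size]
    cohort = CohortConfig(n_subjects=n_subj, sessions_per_phase=n_sess,
                          trials_per_session=n_trials, seed=seed, **overrides)
    return RunConfig(cohort=cohort)


def make_fixture(size: str, outdir, seed: int = 0) -> Path:
    """Write an on-disk fixture cohort (container + truth) for tests."""
    from .synthetic import generate_cohort

    cfg = fixture_config(size, seed)
    return generate_cohort(cfg.cohort, outdir)
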