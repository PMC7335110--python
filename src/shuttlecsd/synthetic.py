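"""Synthetic laminar Go/NoGo cohorts with known ground truth.

The generator emulates the statistical structure of a shuttle-box
experiment: per-trial laminar LFP built from layer-specific sink/source
templates (feedforward latency order: granular III/IV and infragranular Vb
earliest), behavioral outcomes drawn from a logistic decision model with
subject-level random effects, and additive recording noise.

Generative model (per trial, subject s, CS index k = 1..K):

    e ~ N(0, 1)                                  latent response evidence
    eta = bias(contingency) + u_s + (beta + w_s) * e
    respond ~ Bernoulli(logistic(eta))
    m_k = 1 + c * [Go] + a * (1 + g*(k-1)) * e + q_s
    layer amplitude at CS k = base_amp[layer] * (1 + weight[layer]*(m_k - 1))

with u_s ~ N(0, sigma_intercept^2) and w_s ~ N(0, sigma_slope^2) the random
intercept/slope, a = ``evidence_amp``, g = ``accumulation_gain``, c =
``condition_amp`` and q_s a small subject-level amplitude offset.  The
evidence term couples cortical amplitude to the upcoming response in both
contingencies (responded trials show more current flow: hits > misses and
FAs > correct rejections), while the contingency term c raises Go-trial
amplitudes during discrimination.  With c at its default "balanced" value
(see :func:`balanced_condition_amp`) the two couplings cancel between false
alarms and misses, producing the incorrect-choice null by construction.

Randomness is counter-based: every trial draws from a fresh
``numpy.random.default_rng`` seeded by (seed, subject, phase, session,
trial), so any single trial is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrialRecord, classify_outcome
from .signal import (
    CSDProfile,
    LaminarRecording,
    LayerMap,
    LAYERS,
    default_layer_map,
)

#: evoked-onset latencies (s); thalamorecipient III/IV and Vb lead
DEFAULT_LATENCIES = {
    "III/IV": 0.012, "Vb": 0.014, "I/II": 0.022, "Va": 0.026, "VI": 0.030,
}
#: relative sink strengths; granular input dominates
DEFAULT_BASE_AMPLITUDES = {
    "I/II": 0.6, "III/IV": 1.0, "Va": 0.5, "Vb": 0.8, "VI": 0.5,
}

PHASES = ("detection", "discrimination")
GO_FREQ_HZ = 1000.0
NOGO_FREQ_HZ = 4000.0


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Trial timing follows the task design: 200-ms tones at 1.5-s ISI (1.7-s
    onset spacing), a 6-s Go observation window and a 12-15-s NoGo window.
    """

    n_subjects: int = 8
    sessions_per_phase: int = 2
    trials_per_session: int = 60
    n_channels: int = 32
    spacing_um: float = 50.0
    fs_hz: float = 1000.0
    cs_duration_s: float = 0.2
    isi_s: float = 1.5
    go_window_s: float = 6.0
    nogo_window_s: tuple = (12.0, 15.0)
    baseline_s: float = 0.2
    phases: tuple = PHASES

    # decision model (log-odds scale)
    beta_fixed: float = 0.55         # choice coupling per evidence SD
    sigma_intercept: float = 0.5     # SD of subject random intercept
    sigma_slope: float = 0.2         # SD of subject random slope
    go_bias: float = 1.2             # Go response bias (discrimination)
    nogo_bias: float = -1.2          # NoGo response bias (discrimination)
    detection_bias: float = 1.2      # response bias in detection (all Go)

    # amplitude model
    evidence_amp: float = 0.3        # amplitude modulation per evidence SD
    accumulation_gain: float = 0.2   # per-CS-index gain on the evidence term
    condition_amp: float | None = None  # Go amplitude offset; None = balanced
    amp_jitter_sd: float = 0.3       # trial-level multiplicative gain jitter SD
    sigma_amp_subject: float = 0.1   # SD of subject amplitude offset q_s
    layer_weights: dict = field(default_factory=lambda: {l: 1.0 for l in LAYERS})

    noise_sd: float = 0.005          # additive white sensor-noise SD
    ongoing_sd: float = 0.01         # spatially smooth ongoing-activity SD
    ongoing_spatial_sigma: float = 3.0  # channel-wise correlation scale
    its_prob: float = 0.15           # P(>=1 intertrial shuttle per interval)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "sessions_per_phase", "trials_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nogo_window_s[0] > self.nogo_window_s[1]:
            raise ValueError("NoGo window bounds must be ordered")
        for name in ("cs_duration_s", "isi_s", "go_window_s", "baseline_s"):
            samples = getattr(self, name) * self.fs_hz
            if abs(samples - round(samples)) > 1e-9:
                raise ValueError(f"{name} must be an integer number of samples")
        unknown = set(self.layer_weights) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers in layer_weights: {unknown}")
        self.layer_weights = {l: float(self.layer_weights.get(l, 0.0)) for l in LAYERS}

    @property
    def cs_spacing_s(self) -> float:
        return self.cs_duration_s + self.isi_s

    def resolved_condition_amp(self) -> float:
        if self.condition_amp is not None:
            return float(self.condition_amp)
        return balanced_condition_amp(self)

    def layer_map(self) -> LayerMap:
        return default_layer_map(self.n_channels)


def expected_anchor_index(cfg: CohortConfig, contingency: str) -> float:
    """Expected CS index of the choice-locked anchor for responded trials.

    The crossing time is uniform between the second CS onset and the window
    end; the anchor is the last CS onset strictly before it.  For NoGo the
    window length itself is uniform over the configured range.
    """
    sp = cfg.cs_spacing_s
    if contingency == "Go":
        windows = [cfg.go_window_s]
    else:
        windows = np.linspace(*cfg.nogo_window_s, 31)
    ks = []
    for w in windows:
        t = np.linspace(sp, w, 200, endpoint=False) + (w - sp) / 400.0
        ks.append(np.mean(np.ceil(t / sp)))
    return float(np.mean(ks))


def balanced_condition_amp(cfg: CohortConfig) -> float:
    """Contingency amplitude offset that silences the FA-vs-miss contrast.

    False alarms (NoGo responders) sit in the high tail of the evidence
    distribution and misses (Go non-responders) in the low tail, so the
    response-coupled amplitude separates them; the contingency offset c is
    chosen to cancel that separation at the classes' choice-locked anchor
    windows:

        c = a_FA * E[e | respond, NoGo] - a_miss * E[e | no response, Go]

    where a_cls = evidence_amp * (1 + accumulation_gain * (k_cls - 1)) uses
    each class's expected anchor CS index (misses anchor at the 4th CS;
    false-alarm anchors follow the crossing-time distribution).  Conditional
    expectations are Gauss-Hermite quadratures under the logistic response
    model, integrating over the subject random intercept and slope (which
    soften the selection relative to the fixed-effects-only tails).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(48)
    w = weights / weights.sum()
    e_n, u_n, w_n = np.meshgrid(nodes, nodes, nodes, indexing="ij")
    wt = (w[:, None, None] * w[None, :, None] * w[None, None, :])

    def cond_mean(bias: float, respond: bool) -> float:
        eta = bias + cfg.sigma_intercept * u_n \
            + (cfg.beta_fixed + cfg.sigma_slope * w_n) * e_n
        p = _logistic(eta)
        if not respond:
            p = 1.0 - p
        return float(np.sum(wt * e_n * p) / np.sum(wt * p))

    def gain(k: float) -> float:
        return cfg.evidence_amp * (1.0 + cfg.accumulation_gain * (k - 1.0))

    a_fa = gain(expected_anchor_index(cfg, "NoGo"))
    a_miss = gain(4.0)
    e_fa = cond_mean(cfg.nogo_bias, respond=True)
    e_miss = cond_mean(cfg.go_bias, respond=False)
    return a_fa * e_fa - a_miss * e_miss


@dataclass
class SubjectEffects:
    """Per-subject random-effect draws (ground truth)."""

    subject: str
    intercept: float      # u_s, log-odds
    slope: float          # w_s, log-odds per evidence SD
    amp_offset: float     # q_s, relative amplitude


def draw_subject_effects(cfg: CohortConfig) -> list[SubjectEffects]:
    out = []
    for s in range(cfg.n_subjects):
        rng = np.random.default_rng([cfg.seed, s, 0x5EED])
        out.append(SubjectEffects(
            subject=f"s{s:02d}",
            intercept=float(rng.normal(0.0, cfg.sigma_intercept)),
            slope=float(rng.normal(0.0, cfg.sigma_slope)),
            amp_offset=float(rng.normal(0.0, cfg.sigma_amp_subject)),
        ))
    return out


def _alpha_kernel(fs: float, duration: float = 0.35,
                  tau_rise: float = 0.01, tau_decay: float = 0.06) -> np.ndarray:
    """Difference-of-exponentials temporal kernel, peak-normalized to 1."""
    t = np.arange(int(round(duration * fs))) / fs
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / k.max()


def _layer_spatial_profile(layer_map: LayerMap, layer: str, n_channels: int,
                           flank: int = 3) -> np.ndarray:
    """Charge-balanced sink (negative) with flanking sources for one layer."""
    lo, hi = layer_map.bands[layer]
    if hi >= n_channels:
        raise ValueError(f"band {layer} outside channel range")
    prof = np.zeros(n_channels)
    width = hi - lo + 1
    # Hann-shaped sink over the band (never identically zero at width 1)
    sink = -np.sin(np.pi * (np.arange(width) + 0.5) / width)
    prof[lo : hi + 1] = sink
    charge = -sink.sum()
    up = np.arange(max(0, lo - flank), lo)
    down = np.arange(hi + 1, min(n_channels, hi + 1 + flank))
    n_src = up.size + down.size
    if n_src == 0:
        raise ValueError(f"band {layer} spans all channels; no room for sources")
    shape = lambda m: np.sin(np.pi * (np.arange(m) + 0.5) / m)  # noqa: E731
    if up.size:
        s = shape(up.size)
        prof[up] += charge * (up.size / n_src) * s / s.sum()
    if down.size:
        s = shape(down.size)
        prof[down] += charge * (down.size / n_src) * s / s.sum()
    # exact balance: spread any fp residual over the support
    residual = prof.sum()
    support = prof != 0
    if support.any():
        prof[support] -= residual * np.abs(prof[support]) / np.abs(prof[support]).sum()
    return prof


def make_csd_template(
    layer_map: LayerMap,
    latencies: dict | None = None,
    amplitudes: dict | None = None,
    n_channels: int = 32,
    fs: float = 1000.0,
    duration: float = 0.4,
    spacing_um: float = 50.0,
) -> CSDProfile:
    """Build a channels x time evoked CSD template from per-layer components.

    Each layer contributes a sink in its band with flanking return sources,
    sharing a smooth alpha-like time course shifted by the layer's latency.
    Latencies must respect the feedforward order (III/IV and Vb lead).
    Every time column sums to ~0 across channels (charge balance).
    """
    latencies = dict(DEFAULT_LATENCIES if latencies is None else latencies)
    amplitudes = dict(DEFAULT_BASE_AMPLITUDES if amplitudes is None else amplitudes)
    layer_map.validate_against(n_channels)
    early = min(latencies["III/IV"], latencies["Vb"])
    for layer in ("I/II", "Va", "VI"):
        if latencies[layer] < early:
            raise ValueError(
                "latencies must respect the feedforward order "
                "(III/IV and Vb earliest)"
            )
    n_samples = int(round(duration * fs))
    template = np.zeros((n_channels, n_samples))
    for layer in LAYERS:
        amp = float(amplitudes.get(layer, 0.0))
        if amp == 0.0:
            continue
        prof = _layer_spatial_profile(layer_map, layer, n_channels)
        kern = _alpha_kernel(fs)
        onset = int(round(latencies[layer] * fs))
        m = min(kern.size, n_samples - onset)
        if m <= 0:
            continue
        template[:, onset : onset + m] += amp * np.outer(prof, kern[:m])
    return CSDProfile(template, fs=fs, spacing_um=spacing_um, t0=0.0)


def template_to_lfp(template: CSDProfile, spacing_um: float | None = None) -> LaminarRecording:
    """Invert the CSD operator: potential whose second difference is -dz^2*CSD.

    Double cumulative spatial summation with both integration constants set
    to zero (Phi[0] = Phi[1] = 0); the CSD is invariant to that choice.  The
    interior-channel identity compute_csd(template_to_lfp(T)) == T holds to
    numerical precision.
    """
    if spacing_um is None:
        spacing_um = template.spacing_um
    values = np.asarray(template.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("template must be finite")
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 channels")
    dz_mm = spacing_um / 1000.0
    phi = np.zeros_like(values)
    # second difference at channel i: phi[i+1] - 2 phi[i] + phi[i-1] = -dz^2 T[i]
    for i in range(1, n - 1):
        phi[i + 1] = 2.0 * phi[i] - phi[i - 1] - dz_mm**2 * values[i]
    return LaminarRecording(phi, fs=template.fs, spacing_um=spacing_um, t0=template.t0)


def cs_onsets_for_window(window_length: float, cs_spacing: float = 1.7,
                         rms_window: float = 0.5) -> np.ndarray:
    """CS onset times: multiples of the onset spacing whose analysis window fits."""
    n = int(np.floor((window_length - rms_window) / cs_spacing)) + 1
    return np.arange(max(n, 1)) * cs_spacing


@dataclass
class TrialGroundTruth:
    evidence: float
    log_odds: float
    p_respond: float
    amplitude_factors: dict     # layer -> list of per-CS modulation factors


def simulate_trial(
    cfg: CohortConfig,
    effects: SubjectEffects,
    phase: str,
    session: int,
    trial_index: int,
    cs_frequency_hz: float,
    contingency: str,
    base_lfp_template: dict | None = None,
) -> tuple[LaminarRecording, TrialRecord, TrialGroundTruth]:
    """Simulate one trial's laminar LFP and behavioral record.

    ``base_lfp_template`` is an optional cache mapping layer -> LFP of that
    layer's unit-amplitude template (avoids re-inverting the CSD per trial).
    """
    subj_idx = int(effects.subject.lstrip("s"))
    phase_idx = cfg.phases.index(phase)
    rng = np.random.default_rng([cfg.seed, subj_idx, phase_idx, session, trial_index])

    if contingency == "Go":
        window = cfg.go_window_s
    else:
        lo, hi = cfg.nogo_window_s
        window = lo + (hi - lo) * rng.random()
        window = np.round(window * cfg.fs_hz) / cfg.fs_hz
    onsets = cs_onsets_for_window(window, cfg.cs_spacing_s)

    # --- decision model ---
    e = float(rng.normal())
    if phase == "detection":
        bias = cfg.detection_bias
    else:
        bias = cfg.go_bias if contingency == "Go" else cfg.nogo_bias
    eta = bias + effects.intercept + (cfg.beta_fixed + effects.slope) * e
    p = float(_logistic(eta))
    respond = bool(rng.random() < p)
    crossing = None
    if respond and onsets.size >= 2:
        # responses start after the second CS, uniform to the window end
        t_lo = float(onsets[1])
        crossing = t_lo + (window - t_lo) * float(rng.random())
        crossing = float(np.round(crossing * cfg.fs_hz) / cfg.fs_hz)
    elif respond:
        crossing = float(window * rng.random())
    outcome = classify_outcome(contingency, crossing, window, cfg.go_window_s)

    # --- LFP synthesis ---
    n_samples = int(round((cfg.baseline_s + window) * cfg.fs_hz))
    data = np.zeros((cfg.n_channels, n_samples))
    layer_map = cfg.layer_map()
    if base_lfp_template is None:
        base_lfp_template = unit_layer_lfp_templates(cfg)
    c = cfg.resolved_condition_amp() if phase == "discrimination" else 0.0
    go_ind = 1.0 if contingency == "Go" else 0.0
    # trial-level gain jitter: arousal-like amplitude variability shared by
    # all CS of the trial, independent of contingency and choice
    jitter = float(rng.normal(0.0, cfg.amp_jitter_sd)) if cfg.amp_jitter_sd > 0 else 0.0
    amp_factors = {layer: [] for layer in LAYERS}
    for k, onset in enumerate(onsets, start=1):
        if crossing is not None and onset >= crossing:
            break  # CS presentation is terminated by the response
        m_k = c * go_ind + cfg.evidence_amp * (1.0 + cfg.accumulation_gain * (k - 1)) * e \
            + effects.amp_offset + jitter
        i0 = int(round((cfg.baseline_s + onset) * cfg.fs_hz))
        for layer in LAYERS:
            factor = max(1.0 + cfg.layer_weights[layer] * m_k, 0.05)
            amp_factors[layer].append(factor)
            tmpl = base_lfp_template[layer]
            m = min(tmpl.shape[1], n_samples - i0)
            if m > 0:
                data[:, i0 : i0 + m] += factor * tmpl[:, :m]
    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    if cfg.ongoing_sd > 0:
        # ongoing population activity: spatially smooth across depth, so it
        # is largely cancelled by the CSD (unlike sensor noise)
        from scipy.ndimage import gaussian_filter1d

        raw = rng.normal(0.0, 1.0, size=data.shape)
        smooth = gaussian_filter1d(raw, cfg.ongoing_spatial_sigma, axis=0,
                                   mode="nearest")
        smooth /= max(smooth.std(), 1e-12)
        data += cfg.ongoing_sd * smooth

    rec = LaminarRecording(data, fs=cfg.fs_hz, spacing_um=cfg.spacing_um,
                           t0=-cfg.baseline_s)
    trial = TrialRecord(
        subject=effects.subject, session=session, phase=phase,
        trial_id=f"{effects.subject}-{phase}-{session:02d}-{trial_index:03d}",
        cs_frequency_hz=cs_frequency_hz, contingency=contingency,
        window_length_s=float(window), cs_onsets_s=tuple(float(x) for x in onsets),
        crossing_time_s=crossing, outcome=outcome,
        intertrial_shuttle=int(rng.random() < cfg.its_prob),
    )
    truth = TrialGroundTruth(evidence=e, log_odds=float(eta), p_respond=p,
                             amplitude_factors=amp_factors)
    return rec, trial, truth


def unit_layer_lfp_templates(cfg: CohortConfig) -> dict:
    """LFP of each layer's unit-amplitude evoked template (scaled by base amp)."""
    layer_map = cfg.layer_map()
    out = {}
    for layer in LAYERS:
        amps = {l: 0.0 for l in LAYERS}
        amps[layer] = DEFAULT_BASE_AMPLITUDES[layer]
        tmpl = make_csd_template(layer_map, amplitudes=amps,
                                 n_channels=cfg.n_channels, fs=cfg.fs_hz,
                                 spacing_um=cfg.spacing_um)
        out[layer] = template_to_lfp(tmpl).data
    return out


def _session_conditions(cfg: CohortConfig, subj_idx: int, phase: str,
                        session: int) -> list[tuple[float, str]]:
    """Pseudorandomized (frequency, contingency) sequence for one session."""
    phase_idx = cfg.phases.index(phase)
    rng = np.random.default_rng([cfg.seed, subj_idx, phase_idx, session, 0xC0DE])
    n = cfg.trials_per_session
    freqs = np.array([GO_FREQ_HZ] * (n - n // 2) + [NOGO_FREQ_HZ] * (n // 2))
    freqs = rng.permutation(freqs)
    conds = []
    for f in freqs:
        if phase == "detection":
            conds.append((float(f), "Go"))
        else:
            conds.append((float(f), "Go" if f == GO_FREQ_HZ else "NoGo"))
    return conds


def iter_cohort_trials(cfg: CohortConfig, with_truth: bool = False):
    """Stream (recording, trial_record[, truth]) over the whole cohort.

    Trials are generated lazily so a full cohort never has to reside in
    memory; iteration order is deterministic (subject, phase, session, trial).
    """
    effects = draw_subject_effects(cfg)
    templates = unit_layer_lfp_templates(cfg)
    for eff in effects:
        subj_idx = int(eff.subject.lstrip("s"))
        for phase in cfg.phases:
            for session in range(cfg.sessions_per_phase):
                conds = _session_conditions(cfg, subj_idx, phase, session)
                for t, (freq, cont) in enumerate(conds):
                    rec, trial, truth = simulate_trial(
                        cfg, eff, phase, session, t, freq, cont,
                        base_lfp_template=templates,
                    )
                    if with_truth:
                        yield rec, trial, truth
                    else:
                        yield rec, trial


@dataclass
class GroundTruth:
    """Serializable generator ground truth for recovery tests."""

    config: dict
    condition_amp_resolved: float
    subjects: list
    layer_map: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_config(cls, cfg: CohortConfig) -> "GroundTruth":
        d = asdict(cfg)
        d["nogo_window_s"] = list(d["nogo_window_s"])
        d["phases"] = list(d["phases"])
        return cls(
            config=d,
            condition_amp_resolved=cfg.resolved_condition_amp(),
            subjects=[asdict(e) for e in draw_subject_effects(cfg)],
            layer_map={l: list(cfg.layer_map().bands[l]) for l in LAYERS},
        )


def trial_table(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "subject": t.subject, "session": t.session, "phase": t.phase,
            "trial_id": t.trial_id, "cs_frequency_hz": t.cs_frequency_hz,
            "contingency": t.contingency, "window_length_s": t.window_length_s,
            "cs_onsets_s": ";".join(f"{x:.4f}" for x in t.cs_onsets_s),
            "crossing_time_s": t.crossing_time_s if t.crossing_time_s is not None else np.nan,
            "outcome": t.outcome, "intertrial_shuttle": t.intertrial_shuttle,
        })
    return pd.DataFrame(rows)


def generate_cohort(cfg: CohortConfig, outdir) -> Path:
    """Write a full cohort to disk (HDF5 container + trial CSV + truth JSON)."""
    from .io import write_cohort  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        write_cohort(cfg, outdir)
    except OSError as err:
        raise OSError(f"failed writing cohort under {outdir}: {err}") from err
    return outdir


def simulate_logit_dataset(
    n_subjects: int = 8,
    n_trials: int = 500,
    beta: float = 1.0,
    sigma_intercept: float = 1.0,
    sigma_slope: float = 0.0,
    intercept: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct draw from the mixed logistic model (estimator-level oracle data).

    Columns: subject, x (standard-normal predictor), y (0/1).  Used for
    parameter-recovery and type-I checks of the GLMM fitter without the LFP
    measurement layer in between.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(0.0, sigma_intercept, size=n_subjects)
    w = rng.normal(0.0, sigma_slope, size=n_subjects) if sigma_slope > 0 else np.zeros(n_subjects)
    rows = []
    for s in range(n_subjects):
        x = rng.normal(size=n_trials)
        eta = intercept + u[s] + (beta + w[s]) * x
        y = (rng.random(n_trials) < _logistic(eta)).astype(int)
        rows.append(pd.DataFrame({"subject": f"s{s:02d}", "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)
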