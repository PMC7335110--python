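"""Statistical layer: repeated-measures ANOVA, Holm posthoc tests, and
GLMM-based effect-size maps over layers and time.

The repeated-measures ANOVA operates on subject x cell means (single trials
are aggregated first, matching subject-level denominator degrees of
freedom) and reports generalized eta squared,

    eta2_gen = SS_effect / (SS_effect + SS_subjects + sum of all error SS),

the effect-size measure appropriate for fully within-subject designs.
Effect sizes from both families are banded identically: small <= 0.1,
0.1 < medium < 0.25, large >= 0.25.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import MixedLogit, MixedLogitResults
from .signal import LAYERS

P_CATEGORIES = ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"))


def effect_band(value: float) -> str:
    """Band an R2m or eta2_gen effect size: small <=0.1 < medium < 0.25 <= large."""
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"effect size {value} outside [0, 1]")
    if value <= 0.1:
        return "small"
    if value < 0.25:
        return "medium"
    return "large"


def p_category(p: float) -> str:
    for threshold, label in P_CATEGORIES:
        if p < threshold:
            return label
    return "ns"


@dataclass
class AnovaResult:
    factor: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta2_gen: float


def _cell_means(data: pd.DataFrame, dv: str, within: list[str],
                subject: str) -> pd.DataFrame:
    cells = data.groupby([subject, *within], sort=True, observed=True)[dv].mean()
    counts = cells.groupby(level=0).size()
    n_cells = int(np.prod([data[w].nunique() for w in within]))
    incomplete = counts[counts != n_cells]
    if len(incomplete) or cells.isna().any():
        missing = []
        full = pd.MultiIndex.from_product(
            [data[subject].unique(), *[sorted(data[w].unique()) for w in within]]
        )
        missing = [tuple(ix) for ix in full.difference(cells.index)]
        raise ValueError(f"missing design cells for rmANOVA: {missing[:10]}")
    return cells.reset_index()


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str = "subject"
             ) -> list[AnovaResult]:
    """Repeated-measures ANOVA (1 or 2 within factors) on subject-cell means.

    Returns one :class:`AnovaResult` per main effect (and the interaction for
    two factors), with generalized eta squared.  A degenerate design in which
    effect and error sums of squares both vanish yields F = 0, p = 1.
    """
    within = [within] if isinstance(within, str) else list(within)
    if len(within) not in (1, 2):
        raise ValueError("rm_anova supports 1 or 2 within factors")
    cells = _cell_means(data, dv, within, subject)
    y = cells[dv].to_numpy(dtype=float)
    grand = y.mean()
    n_s = cells[subject].nunique()

    def ss_of(groupers) -> float:
        m = cells.groupby(groupers, observed=True)[dv].transform("mean")
        return float(np.sum((m - grand) ** 2))

    ss_subj = ss_of([subject])
    ss_total = float(np.sum((y - grand) ** 2))

    if len(within) == 1:
        a = within[0]
        ka = cells[a].nunique()
        ss_a = ss_of([a])
        ss_err = ss_total - ss_a - ss_subj
        effects = [(a, ss_a, ka - 1, (ka - 1) * (n_s - 1), ss_err)]
        error_ss_total = ss_err
    else:
        a, b = within
        ka, kb = cells[a].nunique(), cells[b].nunique()
        ss_a, ss_b = ss_of([a]), ss_of([b])
        ss_ab = ss_of([a, b]) - ss_a - ss_b
        ss_as = ss_of([subject, a]) - ss_a - ss_subj
        ss_bs = ss_of([subject, b]) - ss_b - ss_subj
        ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_subj - ss_as - ss_bs
        effects = [
            (a, ss_a, ka - 1, (ka - 1) * (n_s - 1), ss_as),
            (b, ss_b, kb - 1, (kb - 1) * (n_s - 1), ss_bs),
            (f"{a}:{b}", ss_ab, (ka - 1) * (kb - 1),
             (ka - 1) * (kb - 1) * (n_s - 1), ss_abs),
        ]
        error_ss_total = ss_as + ss_bs + ss_abs

    results = []
    for name, ss_eff, dfn, dfd, ss_err in effects:
        ms_eff = ss_eff / dfn if dfn else 0.0
        ms_err = ss_err / dfd if dfd else 0.0
        if ms_err <= 1e-300:
            f_val, p = (0.0, 1.0) if ss_eff <= 1e-300 else (np.inf, 0.0)
        else:
            f_val = ms_eff / ms_err
            p = float(stats.f.sf(f_val, dfn, dfd))
        denom = ss_eff + ss_subj + error_ss_total
        eta2 = float(ss_eff / denom) if denom > 0 else 0.0
        results.append(AnovaResult(name, float(f_val), dfn, dfd, p, eta2))
    return results


def holm_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction: (reject decisions, adjusted p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def paired_t(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test on subject-matched values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 matched pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise ValueError("zero variance of nonzero differences; t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class GLMMSpec:
    """Definition of one mixed-logit comparison.

    ``classes``: (reference, target) labels of the column ``class_col``; the
    target class is coded 1.  One z-scored RMS feature is the sole fixed
    predictor, grouped by subject.
    """

    classes: tuple
    class_col: str = "outcome"
    predictor: str = "rms_z"
    group: str = "subject"
    random_slope: bool = True


@dataclass
class EffectSize:
    r2m: float
    r2c: float
    band: str
    p: float
    p_category: str
    beta: float
    beta_se: float
    n_obs: int
    n_groups: int
    converged: bool


def fit_glmm(data: pd.DataFrame, spec: GLMMSpec) -> MixedLogitResults:
    """Fit the mixed logit of class membership on one feature column."""
    sub = data[data[spec.class_col].isin(spec.classes)].copy()
    present = set(sub[spec.class_col].unique())
    if len(present) < 2:
        raise ValueError(f"both classes required, found only {sorted(present)}")
    sub["_y"] = (sub[spec.class_col] == spec.classes[1]).astype(int)
    model = MixedLogit.from_dataframe(sub, "_y", spec.predictor, spec.group,
                                      random_slope=spec.random_slope)
    return model.fit()


def effect_size_from_fit(fit: MixedLogitResults) -> EffectSize:
    r2m, r2c = fit.r2_nakagawa()
    p = float(fit.pvalues[1])
    return EffectSize(
        r2m=r2m, r2c=r2c, band=effect_band(r2m), p=p, p_category=p_category(p),
        beta=float(fit.params[1]), beta_se=float(fit.bse[1]),
        n_obs=fit.n_obs, n_groups=fit.n_groups, converged=fit.converged,
    )


def _select_rows(features: pd.DataFrame, layer: str, window_kind: str,
                 back_k: int | None = None, phase: str | None = None
                 ) -> pd.DataFrame:
    sel = (features["layer"] == layer) & (features["window_kind"] == window_kind)
    if back_k is not None:
        sel &= features["back_k"] == back_k
    if phase is not None:
        sel &= features["phase"] == phase
    return features[sel]


def layer_predictability_map(
    features: pd.DataFrame,
    spec: GLMMSpec,
    window_kind: str = "choice_locked",
    back_k: int | None = 0,
    phase: str | None = None,
    layers=LAYERS,
    min_per_class: int = 5,
) -> tuple[dict, str | None]:
    """One GLMM per laminar signal; returns ({layer: EffectSize}, argmax layer).

    Layers whose fit fails are reported as None (the map is still returned
    with gaps flagged).  R2max ties break superficial-to-deep in the layer
    order given.
    """
    out: dict = {}
    best_layer, best_r2 = None, -1.0
    for layer in layers:
        sub = _select_rows(features, layer, window_kind, back_k, phase)
        counts = sub[sub[spec.class_col].isin(spec.classes)][spec.class_col].value_counts()
        if len(counts) < 2 or counts.min() < min_per_class:
            out[layer] = None
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                es = effect_size_from_fit(fit_glmm(sub, spec))
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            out[layer] = None
            continue
        out[layer] = es
        if es.r2m > best_r2 + 1e-12:  # strict: earlier (more superficial) wins ties
            best_layer, best_r2 = layer, es.r2m
    return out, best_layer


def timeresolved_effects(
    features: pd.DataFrame,
    spec: GLMMSpec,
    ks=(3, 2, 1, 0),
    phase: str | None = None,
    layers=("AVREC",) + LAYERS,
    min_per_class: int = 5,
) -> pd.DataFrame:
    """GLMM effect sizes per (layer, response - k CS) bin; no smoothing.

    Bins with too few trials in either class are reported absent (NaN).
    """
    rows = []
    for layer, k in itertools.product(layers, ks):
        sub = _select_rows(features, layer, "choice_locked", k, phase)
        counts = sub[sub[spec.class_col].isin(spec.classes)][spec.class_col].value_counts()
        es = None
        if len(counts) == 2 and counts.min() >= min_per_class:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    es = effect_size_from_fit(fit_glmm(sub, spec))
            except (ValueError, RuntimeError, np.linalg.LinAlgError):
                es = None
        rows.append({
            "layer": layer, "back_k": k,
            "r2m": es.r2m if es else np.nan,
            "r2c": es.r2c if es else np.nan,
            "band": es.band if es else None,
            "p": es.p if es else np.nan,
            "p_category": es.p_category if es else None,
            "n_obs": es.n_obs if es else 0,
        })
    return pd.DataFrame(rows)
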