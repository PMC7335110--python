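"""rmANOVA, Holm posthoc, paired t, effect banding and effect-size maps."""

import numpy as np
import pandas as pd
import pytest

from shuttlecsd.inference import (
    GLMMSpec,
    effect_band,
    fit_glmm,
    holm_correct,
    layer_predictability_map,
    p_category,
    paired_t,
    rm_anova,
)


def _long(values, subjects, factors):
    """values[s, a(, b)] -> tidy frame."""
    rows = []
    it = np.ndindex(values.shape)
    for idx in it:
        row = {"subject": subjects[idx[0]], "v": values[idx]}
        for name, i in zip(factors, idx[1:]):
            row[name] = f"{name}{i}"
        rows.append(row)
    return pd.DataFrame(rows)


def _oracle_oneway(values):
    """Independent sums-of-squares evaluation of the one-way rmANOVA."""
    n_s, k = values.shape
    grand = values.mean()
    ss_a = n_s * ((values.mean(axis=0) - grand) ** 2).sum()
    ss_s = k * ((values.mean(axis=1) - grand) ** 2).sum()
    ss_t = ((values - grand) ** 2).sum()
    ss_e = ss_t - ss_a - ss_s
    dfn, dfd = k - 1, (k - 1) * (n_s - 1)
    F = (ss_a / dfn) / (ss_e / dfd)
    from scipy.stats import f as fdist

    p = fdist.sf(F, dfn, dfd)
    eta = ss_a / (ss_a + ss_s + ss_e)
    return F, p, eta


class TestRmAnova:
    def test_identical_conditions_give_null_result(self):
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 2))
        res = rm_anova(_long(vals, ["a", "b", "c"], ["cond"]), "v", "cond")
        assert res[0].F == 0.0 and res[0].p == 1.0

    def test_matches_oracle_one_way(self, rng):
        vals = rng.normal(size=(5, 3))
        res = rm_anova(_long(vals, list("abcde"), ["cond"]), "v", "cond")[0]
        F, p, eta = _oracle_oneway(vals)
        assert res.F == pytest.approx(F, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)
        assert res.eta2_gen == pytest.approx(eta, abs=1e-10)
        assert (res.df_num, res.df_den) == (2, 8)

    def test_matches_pingouin_two_way(self, rng):
        pingouin = pytest.importorskip("pingouin")
        vals = rng.normal(size=(6, 2, 4))
        df = _long(vals, list("abcdef"), ["out", "tone"])
        mine = {r.factor: r for r in rm_anova(df, "v", ["out", "tone"])}
        ref = pingouin.rm_anova(data=df, dv="v", within=["out", "tone"],
                                subject="subject", detailed=True,
                                effsize="ng2")
        for factor, key in (("out", "out"), ("tone", "tone"),
                            ("out:tone", "out * tone")):
            row = ref[ref["Source"] == key].iloc[0]
            assert mine[factor].F == pytest.approx(row["F"], abs=1e-8)
            assert mine[factor].p == pytest.approx(row["p_unc"], abs=1e-8)
            assert mine[factor].eta2_gen == pytest.approx(row["ng2"], abs=1e-8)

    def test_trials_aggregated_to_subject_cells(self, rng):
        # replicated trials per cell must not inflate the dfs
        vals = rng.normal(size=(4, 3))
        df = _long(vals, list("abcd"), ["cond"])
        trials = pd.concat([df, df.assign(v=df["v"] + rng.normal(0, 1e-9, len(df)))])
        res = rm_anova(trials, "v", "cond")[0]
        assert (res.df_num, res.df_den) == (2, 6)

    def test_eta2_bounds_fuzz(self, rng):
        for _ in range(200):
            vals = rng.normal(size=(4, 3))
            for r in rm_anova(_long(vals, list("abcd"), ["cond"]), "v", "cond"):
                assert 0.0 <= r.eta2_gen <= 1.0

    def test_missing_cell_named(self):
        vals = np.arange(6.0).reshape(3, 2)
        df = _long(vals, list("abc"), ["cond"]).iloc[:-1]
        with pytest.raises(ValueError, match="missing design cells"):
            rm_anova(df, "v", "cond")


def _holm_oracle(p, alpha=0.05):
    order = np.argsort(p)
    m = len(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return reject, adj


class TestHolm:
    def test_single_p(self):
        reject, adj = holm_correct([0.03])
        assert reject[0] and adj[0] == pytest.approx(0.03)

    def test_stepwise_all_rejected(self):
        reject, adj = holm_correct([0.01, 0.02, 0.04])
        assert reject.all()
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_first_step_failure_blocks_all(self):
        reject, _ = holm_correct([0.03, 0.04])
        assert not reject.any()

    def test_empty_input(self):
        reject, adj = holm_correct([])
        assert reject.size == 0 and adj.size == 0

    def test_matches_threshold_oracle_fuzz(self, rng):
        for _ in range(300):
            p = rng.random(rng.integers(1, 8))
            reject, adj = holm_correct(p)
            o_rej, o_adj = _holm_oracle(p)
            assert np.array_equal(reject, o_rej)
            assert np.allclose(adj, o_adj, atol=1e-12)

    def test_dominates_bonferroni(self, rng):
        for _ in range(100):
            p = rng.random(6)
            reject, _ = holm_correct(p)
            bonf = p <= 0.05 / 6
            assert np.all(reject[bonf])


class TestPairedT:
    def test_identical_vectors(self):
        t, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_textbook_formula(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        p_manual = 2 * tdist.sf(abs(t_manual), len(d) - 1)
        t, p = paired_t(a, b)
        assert t == pytest.approx(t_manual, abs=1e-12)
        assert p == pytest.approx(p_manual, abs=1e-12)


class TestEffectBand:
    @pytest.mark.parametrize("value, band", [
        (0.0, "small"), (0.10, "small"), (0.10001, "medium"),
        (0.18, "medium"), (0.2499, "medium"), (0.25, "large"), (0.9, "large"),
    ])
    def test_boundaries(self, value, band):
        assert effect_band(value) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            effect_band(1.2)

    def test_p_categories(self):
        assert p_category(0.0005) == "<0.001"
        assert p_category(0.005) == "<0.01"
        assert p_category(0.03) == "<0.05"
        assert p_category(0.2) == "ns"


def _feature_frame(rng, effects_by_layer, n_subj=6, n_trials=120):
    """Synthetic choice-locked feature rows with per-layer effect sizes."""
    from shuttlecsd.signal import LAYERS

    rows = []
    for s in range(n_subj):
        u = rng.normal(0, 0.4)
        for t in range(n_trials):
            x_base = rng.normal()
            y = rng.random() < 1 / (1 + np.exp(-(u + 1.2 * x_base)))
            for layer in LAYERS:
                w = effects_by_layer.get(layer, 0.0)
                x = w * x_base + np.sqrt(max(1 - w**2, 0.0)) * rng.normal()
                rows.append({
                    "subject": f"s{s}", "layer": layer,
                    "window_kind": "choice_locked", "back_k": 0,
                    "phase": "discrimination",
                    "outcome": "hit" if y else "miss", "rms_z": x,
                })
    return pd.DataFrame(rows)


class TestPredictabilityMap:
    def test_effect_confined_to_supragranular(self, rng):
        df = _feature_frame(rng, {"I/II": 0.9})
        emap, best = layer_predictability_map(
            df, GLMMSpec(classes=("miss", "hit"), random_slope=False))
        assert best == "I/II"
        assert emap["I/II"].r2m > max(
            v.r2m for k, v in emap.items() if k != "I/II")

    def test_null_cohort_all_small(self, rng):
        df = _feature_frame(rng, {})
        emap, _ = layer_predictability_map(
            df, GLMMSpec(classes=("miss", "hit"), random_slope=False))
        for v in emap.values():
            assert v.band == "small"

    def test_tie_breaks_superficial_first(self, rng):
        # identical predictor in every layer -> identical fits -> first wins
        from shuttlecsd.signal import LAYERS

        base = _feature_frame(rng, {"I/II": 0.8})
        ref = base[base.layer == "I/II"]
        tied = pd.concat(
            [ref.assign(layer=l) for l in LAYERS], ignore_index=True)
        _, best = layer_predictability_map(
            tied, GLMMSpec(classes=("miss", "hit"), random_slope=False))
        assert best == "I/II"

    def test_missing_class_reported_as_gap(self, rng):
        df = _feature_frame(rng, {"I/II": 0.5})
        df = df[~((df.layer == "Va") & (df.outcome == "miss"))]
        emap, _ = layer_predictability_map(
            df, GLMMSpec(classes=("miss", "hit"), random_slope=False))
        assert emap["Va"] is None
        assert emap["I/II"] is not None


class TestFitGlmmWrapper:
    def test_single_class_raises(self, rng):
        df = _feature_frame(rng, {"I/II": 0.5})
        only_hit = df[df.outcome == "hit"]
        with pytest.raises(ValueError, match="classes"):
            fit_glmm(only_hit, GLMMSpec(classes=("miss", "hit")))

    def test_class_coding_direction(self, rng):
        df = _feature_frame(rng, {"I/II": 0.9})
        sub = df[df.layer == "I/II"]
        fit = fit_glmm(sub, GLMMSpec(classes=("miss", "hit"),
                                     random_slope=False))
        assert fit.params[1] > 0  # hits coded 1 sit at higher rms_z
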