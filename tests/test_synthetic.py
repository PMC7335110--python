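"""Generator correctness: templates, CSD/LFP inversion, decision model."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from shuttlecsd.signal import compute_csd, default_layer_map, LAYERS
from shuttlecsd.synthetic import (
    CohortConfig,
    balanced_condition_amp,
    cs_onsets_for_window,
    draw_subject_effects,
    generate_cohort,
    iter_cohort_trials,
    make_csd_template,
    simulate_logit_dataset,
    simulate_trial,
    template_to_lfp,
    trial_table,
)


class TestTemplate:
    def test_zero_amplitudes_give_zero_template(self, layer_map32):
        t = make_csd_template(layer_map32, amplitudes={l: 0.0 for l in LAYERS})
        assert np.all(t.values == 0.0)

    def test_granular_only_template_is_local(self, layer_map32):
        amps = {l: 0.0 for l in LAYERS}
        amps["III/IV"] = 1.0
        t = make_csd_template(layer_map32, amplitudes=amps)
        lo, hi = layer_map32.bands["III/IV"]
        flank = 3
        outside = np.ones(32, dtype=bool)
        outside[max(0, lo - flank): hi + 1 + flank] = False
        assert np.all(t.values[outside] == 0.0)
        assert np.abs(t.values[lo: hi + 1]).max() > 0

    def test_charge_balance_per_column(self, layer_map32):
        t = make_csd_template(layer_map32)
        col_sums = np.abs(t.values.sum(axis=0))
        assert col_sums.max() <= 1e-9 * np.abs(t.values).max()

    def test_feedforward_latency_order_enforced(self, layer_map32):
        bad = {"III/IV": 0.03, "Vb": 0.03, "I/II": 0.01, "Va": 0.04, "VI": 0.05}
        with pytest.raises(ValueError, match="feedforward"):
            make_csd_template(layer_map32, latencies=bad)

    def test_sinks_negative_in_band(self, layer_map32):
        t = make_csd_template(layer_map32)
        lo, hi = layer_map32.bands["III/IV"]
        peak_sample = np.abs(t.values[(lo + hi) // 2]).argmax()
        assert t.values[(lo + hi) // 2, peak_sample] < 0


class TestLfpInversion:
    def test_zero_template_gives_constant_potential(self, layer_map32):
        t = make_csd_template(layer_map32, amplitudes={l: 0.0 for l in LAYERS})
        rec = template_to_lfp(t)
        assert np.all(rec.data == 0.0)

    def test_roundtrip_identity_on_interior(self, layer_map32):
        t = make_csd_template(layer_map32)
        rec = template_to_lfp(t)
        back = compute_csd(rec)
        scale = np.abs(t.values).max()
        err = np.abs(back.values[1:-1] - t.values[1:-1]).max()
        assert err <= 1e-9 * scale

    def test_impulse_green_function_piecewise_linear(self):
        from shuttlecsd.signal import CSDProfile

        vals = np.zeros((9, 1))
        vals[4, 0] = 1.0
        rec = template_to_lfp(CSDProfile(vals, fs=1000.0, spacing_um=1000.0))
        phi = rec.data[:, 0]
        # second difference zero away from the impulse -> linear segments
        d2 = phi[2:] - 2 * phi[1:-1] + phi[:-2]
        assert d2[3] == pytest.approx(-1.0, abs=1e-12)  # dz = 1 mm
        assert np.allclose(np.delete(d2, 3), 0.0, atol=1e-12)

    def test_too_few_channels_rejected(self):
        from shuttlecsd.signal import CSDProfile

        with pytest.raises(ValueError, match="3 channels"):
            template_to_lfp(CSDProfile(np.zeros((2, 4)), fs=1000.0))


class TestTrialTiming:
    def test_go_window_has_four_onsets(self):
        onsets = cs_onsets_for_window(6.0)
        assert np.allclose(onsets, [0.0, 1.7, 3.4, 5.1])

    def test_nogo_onsets_fill_window(self):
        onsets = cs_onsets_for_window(13.0)
        assert onsets[-1] <= 12.5
        assert onsets[-1] == pytest.approx(11.9)

    def test_timing_must_align_to_sample_grid(self):
        with pytest.raises(ValueError, match="integer number of samples"):
            CohortConfig(isi_s=1.5003, fs_hz=1000.0)


def _fast_cfg(**kw):
    base = dict(n_subjects=2, sessions_per_phase=1, trials_per_session=10,
                n_channels=16, fs_hz=250.0, seed=5)
    base.update(kw)
    return CohortConfig(**base)


class TestDecisionModel:
    def test_same_seed_is_bit_identical(self):
        cfg = _fast_cfg()
        eff = draw_subject_effects(cfg)[0]
        a = simulate_trial(cfg, eff, "detection", 0, 3, 1000.0, "Go")
        b = simulate_trial(cfg, eff, "detection", 0, 3, 1000.0, "Go")
        assert np.array_equal(a[0].data, b[0].data)
        assert a[1] == b[1]

    def test_noise_free_trials_identical_given_same_modulation(self):
        cfg = _fast_cfg(noise_sd=0.0, ongoing_sd=0.0, amp_jitter_sd=0.0,
                        evidence_amp=0.0, sigma_amp_subject=0.0,
                        accumulation_gain=0.0, condition_amp=0.0)
        eff = draw_subject_effects(cfg)[0]
        eff.amp_offset = 0.0
        recs = []
        for t in range(4):
            rec, trial, _ = simulate_trial(cfg, eff, "detection", 0, t,
                                           1000.0, "Go")
            if trial.outcome == "miss":  # no truncation by a crossing
                recs.append(rec.data)
        assert len(recs) >= 2
        for r in recs[1:]:
            assert np.allclose(r, recs[0], atol=1e-12)

    def test_neutral_model_responds_at_chance(self):
        cfg = _fast_cfg(beta_fixed=0.0, sigma_intercept=0.0, sigma_slope=0.0,
                        detection_bias=0.0, n_channels=16, fs_hz=250.0,
                        trials_per_session=1000, n_subjects=2,
                        phases=("detection",))
        responded = 0
        n = 0
        for _, trial in iter_cohort_trials(cfg):
            responded += trial.outcome == "hit"
            n += 1
        assert n == 2000
        assert 0.47 <= responded / n <= 0.53

    def test_crossings_start_after_second_cs(self):
        cfg = _fast_cfg(trials_per_session=30)
        times = [t.crossing_time_s for _, t in iter_cohort_trials(cfg)
                 if t.crossing_time_s is not None]
        assert times and min(times) >= 1.7

    def test_balanced_condition_amp_matches_empirical_tails(self):
        """The quadrature behind the FA/miss-silencing offset agrees with a
        Monte-Carlo evaluation of the same conditional expectations."""
        cfg = CohortConfig(seed=0)
        rng = np.random.default_rng(99)
        n = 400_000
        e = rng.normal(size=n)
        u = rng.normal(0, cfg.sigma_intercept, size=n)
        w = rng.normal(0, cfg.sigma_slope, size=n)
        eta_nogo = cfg.nogo_bias + u + (cfg.beta_fixed + w) * e
        eta_go = cfg.go_bias + u + (cfg.beta_fixed + w) * e
        resp_nogo = rng.random(n) < 1 / (1 + np.exp(-eta_nogo))
        resp_go = rng.random(n) < 1 / (1 + np.exp(-eta_go))
        e_fa = e[resp_nogo].mean()
        e_miss = e[~resp_go].mean()
        from shuttlecsd.synthetic import expected_anchor_index

        gain = lambda k: cfg.evidence_amp * (1 + cfg.accumulation_gain * (k - 1))  # noqa: E731
        mc = gain(expected_anchor_index(cfg, "NoGo")) * e_fa - gain(4.0) * e_miss
        assert balanced_condition_amp(cfg) == pytest.approx(mc, abs=0.02)


class TestBetaMonotonicity:
    @staticmethod
    def _separation(beta):
        from shuttlecsd.features import PreprocessParams, build_feature_table

        cfg = CohortConfig(n_subjects=2, sessions_per_phase=1,
                           trials_per_session=60, n_channels=16, fs_hz=250.0,
                           phases=("discrimination",), noise_sd=0.0,
                           ongoing_sd=0.0, amp_jitter_sd=0.0,
                           sigma_amp_subject=0.0, beta_fixed=beta, seed=31)
        # noise-free traces have zero MAD, so disable amplitude screening
        params = PreprocessParams(artifact_sd_threshold=1e12)
        f, _ = build_feature_table(iter_cohort_trials(cfg), cfg.layer_map(),
                                   params)
        rows = f[(f.layer == "AVREC") & (f.window_kind == "whole_trace")]
        return (rows[rows.contingency == "Go"]["rms_raw"].mean()
                - rows[rows.contingency == "NoGo"]["rms_raw"].mean())

    def test_go_nogo_separation_grows_with_choice_coupling(self):
        """On noise-free cohorts, a stronger evidence coupling (and its
        balanced contingency offset) widens the Go/NoGo AVREC-RMS gap."""
        seps = [self._separation(b) for b in (0.2, 0.6, 1.2)]
        assert seps[0] < seps[1] < seps[2]
        assert seps[0] > 0

    def test_balanced_offset_monotone_in_beta(self):
        cfgs = [CohortConfig(beta_fixed=b, seed=0) for b in (0.2, 0.6, 1.2)]
        cs = [balanced_condition_amp(c) for c in cfgs]
        assert cs[0] < cs[1] < cs[2]


class TestCohort:
    def test_trial_count(self, tmp_path):
        cfg = _fast_cfg(n_subjects=2, sessions_per_phase=1,
                        trials_per_session=10, phases=("detection",))
        out = generate_cohort(cfg, tmp_path / "c")
        import pandas as pd

        table = pd.read_csv(out / "trials.csv")
        assert len(table) == 20

    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = _fast_cfg(trials_per_session=4)
        for sub in ("a", "b"):
            generate_cohort(cfg, tmp_path / sub)
        for name in ("recordings.h5", "trials.csv", "ground_truth.json"):
            ha = hashlib.sha256((tmp_path / "a" / name).read_bytes()).hexdigest()
            hb = hashlib.sha256((tmp_path / "b" / name).read_bytes()).hexdigest()
            assert ha == hb, name

    def test_random_intercept_sd_recovered_over_subjects(self):
        cfg = CohortConfig(n_subjects=50, sigma_intercept=0.5, seed=123)
        draws = [e.intercept for e in draw_subject_effects(cfg)]
        sd = np.std(draws, ddof=1)
        assert abs(sd - 0.5) <= 0.25 * 0.5

    def test_outcomes_match_stored_probabilities(self):
        """Empirical response rate tracks the mean generated probability."""
        cfg = _fast_cfg(trials_per_session=300, phases=("detection",))
        ps, ys = [], []
        for _, trial, truth in iter_cohort_trials(cfg, with_truth=True):
            ps.append(truth.p_respond)
            ys.append(trial.outcome == "hit")
        assert abs(np.mean(ps) - np.mean(ys)) < 0.04


class TestLogitSimulator:
    def test_shapes_and_classes(self):
        df = simulate_logit_dataset(4, 50, seed=1)
        assert len(df) == 200
        assert set(df["y"].unique()) == {0, 1}

    def test_beta_zero_balanced(self):
        df = simulate_logit_dataset(4, 2000, beta=0.0, sigma_intercept=0.0,
                                    seed=2)
        assert 0.47 <= df["y"].mean() <= 0.53
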