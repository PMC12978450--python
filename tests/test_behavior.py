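"""Behavioral response quantification and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _helpers import null_synth_config, toy_responses, toy_trials
from callcode import ClassifierConfig, SynthConfig
from callcode.behavior import (
    BEHAVIOR_FEATURES,
    behavioral_features,
    classify_familiarity_behavior,
    minmax_normalize_per_group,
    paired_condition_test,
    response_time_distribution,
)
from callcode.config import FAMILIAR, UNFAMILIAR
from callcode.synthgen import gen_behavior_session


class TestResponseTimeDistribution:
    def test_no_responses_gives_zero_histogram(self):
        trials = toy_trials(8)
        _, hist = response_time_distribution(trials, toy_responses({}, trials), bin_ms=50)
        assert np.all(hist == 0)

    def test_point_mass_latency(self):
        trials = toy_trials(6)
        resp = toy_responses({i: 305.0 for i in range(6)}, trials)  # mid-bin
        edges, hist = response_time_distribution(trials, resp, bin_ms=50)
        assert hist[np.flatnonzero(edges == 300)[0]] == 1.0
        assert hist.sum() == 1.0

    def test_mass_equals_answered_fraction(self):
        trials = toy_trials(10)
        resp = toy_responses({0: 120.0, 3: 510.0, 7: 880.0}, trials)
        _, hist = response_time_distribution(trials, resp, bin_ms=100)
        assert hist.sum() == pytest.approx(0.3)

    def test_overlapping_trials_rejected(self):
        trials = toy_trials(4)
        trials.loc[1, "onset_s"] = 0.05
        with pytest.raises(ValueError, match="overlap"):
            response_time_distribution(trials.sort_values("onset_s"), toy_responses({}, trials))

    def test_indivisible_bin_rejected(self):
        trials = toy_trials(4)
        with pytest.raises(ValueError, match="divide"):
            response_time_distribution(trials, toy_responses({}, trials), bin_ms=70)

    def test_histogram_matches_truncated_normal_cdf(self):
        """Generated latency histogram agrees bin-wise with the analytic
        truncated-normal CDF differences."""
        cfg = SynthConfig(seed=17, n_days=1, n_blocks=100, reps_per_block=10,
                          n_unfamiliar_per_bird=1)
        cfg.resp_prob = {FAMILIAR: 1.0, UNFAMILIAR: 1.0}
        s = gen_behavior_session(cfg, 0)
        fam = s.trials[s.trials["familiarity"] == FAMILIAR].reset_index(drop=True)
        edges, hist = response_time_distribution(
            fam, s.responses, bin_ms=50, span_ms=cfg.trial_period_ms
        )
        mu, sd = cfg.latency_mean_ms[FAMILIAR], cfg.latency_sd_ms[FAMILIAR]
        a, b = (0 - mu) / sd, (cfg.trial_period_ms - mu) / sd
        cdf = stats.truncnorm.cdf(np.append(edges, cfg.trial_period_ms), a, b, loc=mu, scale=sd)
        expected = np.diff(cdf)
        n = len(fam)
        sem = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(hist - expected) <= 3 * sem + 1e-9)


class TestBehavioralFeatures:
    def test_hand_computed_example(self):
        trials = toy_trials(10)
        resp = toy_responses({0: 150.0, 1: 250.0, 2: 350.0}, trials)  # mid-bin
        f = behavioral_features(trials, resp, "bird0", bin_ms=100).iloc[0]
        assert f["response_latency_ms"] == pytest.approx(250.0, abs=1e-6)
        assert f["peak_response_prob"] == pytest.approx(0.1)
        assert f["n_responses"] == 3

    def test_identical_latencies_zero_variability(self):
        trials = toy_trials(10)
        resp = toy_responses({0: 250.0, 4: 250.0, 8: 250.0}, trials)
        f = behavioral_features(trials, resp, "b", bin_ms=50).iloc[0]
        assert f["latency_variability_ms"] == pytest.approx(0.0, abs=1e-6)

    def test_undefined_latency_flagged_nan(self):
        trials = toy_trials(5)
        f = behavioral_features(trials, toy_responses({}, trials), "b").iloc[0]
        assert np.isnan(f["response_latency_ms"])
        assert np.isnan(f["latency_variability_ms"])
        assert f["peak_response_prob"] == 0.0

    def test_feature_recovery_from_generator(self):
        """Feature means over replicate birds recover the generating
        parameters (median latency, truncated-normal spread, per-bin peak
        probability) within 3 sem."""
        cfg = SynthConfig(seed=99)
        feats = pd.concat(
            [
                behavioral_features(s.trials, s.responses, s.bird_id)
                for s in (gen_behavior_session(cfg, b) for b in range(12))
            ],
            ignore_index=True,
        )
        span = cfg.trial_period_ms
        for level in (FAMILIAR, UNFAMILIAR):
            sub = feats[feats["familiarity"] == level]
            mu, sd = cfg.latency_mean_ms[level], cfg.latency_sd_ms[level]
            a, b = (0 - mu) / sd, (span - mu) / sd
            target_median = stats.truncnorm.ppf(0.5, a, b, loc=mu, scale=sd)
            vals = sub["response_latency_ms"].dropna()
            assert abs(vals.mean() - target_median) < 3 * vals.std() / np.sqrt(len(vals))
            target_sd = stats.truncnorm.std(a, b, loc=mu, scale=sd)
            vv = sub["latency_variability_ms"].dropna()
            assert abs(vv.mean() - target_sd) < 3 * vv.std() / np.sqrt(len(vv))


class TestPairedConditionTest:
    def test_exact_all_positive_pairs(self):
        """Six all-positive paired differences give the exact two-sided
        signed-rank p of 2/64."""
        feats = pd.DataFrame(
            {
                "bird_id": [f"b{i}" for i in range(6)] * 2,
                "familiarity": [FAMILIAR] * 6 + [UNFAMILIAR] * 6,
                "x": [1, 2, 3, 4, 5, 6] + [0] * 6,
            }
        )
        stat, p, degenerate = paired_condition_test(feats, "x")
        assert p == pytest.approx(0.03125)
        assert not degenerate

    def test_identical_pairs_degenerate(self):
        feats = pd.DataFrame(
            {
                "bird_id": ["a", "b", "c"] * 2,
                "familiarity": [FAMILIAR] * 3 + [UNFAMILIAR] * 3,
                "x": [1.0, 2.0, 3.0] * 2,
            }
        )
        _, p, degenerate = paired_condition_test(feats, "x")
        assert degenerate and p == 1.0

    def test_too_few_pairs_rejected(self):
        feats = pd.DataFrame(
            {"bird_id": ["a", "a"], "familiarity": [FAMILIAR, UNFAMILIAR], "x": [1.0, 0.0]}
        )
        with pytest.raises(ValueError):
            paired_condition_test(feats, "x")

    def test_type_i_error_calibrated(self):
        """Under exchangeable conditions the signed-rank test rejects at the
        nominal rate."""
        rej = 0
        n_rep = 200
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            vals = rng.standard_normal((8, 2))
            feats = pd.DataFrame(
                {
                    "bird_id": [f"b{i}" for i in range(8)] * 2,
                    "familiarity": [FAMILIAR] * 8 + [UNFAMILIAR] * 8,
                    "x": np.concatenate([vals[:, 0], vals[:, 1]]),
                }
            )
            _, p, _ = paired_condition_test(feats, "x")
            rej += p < 0.05
        assert 0.02 * n_rep <= rej <= 0.08 * n_rep


class TestClassifier:
    def _features(self, rng, n_birds=9, separable=False):
        rows = []
        for b in range(n_birds):
            for j, fam in enumerate([FAMILIAR] + [UNFAMILIAR] * 3):
                base = 1.0 if (fam == FAMILIAR and separable) else 0.0
                rows.append(
                    {
                        "bird_id": f"b{b}",
                        "stimulus_id": f"s{b}_{j}",
                        "familiarity": fam,
                        "peak_response_prob": base + 0.1 * rng.random(),
                        "response_latency_ms": 300 - 100 * base + 10 * rng.random(),
                        "latency_variability_ms": 250 - 50 * base + 10 * rng.random(),
                        "n_responses": 10,
                    }
                )
        return pd.DataFrame(rows)

    def test_perfectly_separable(self, rng):
        feats = self._features(rng, separable=True)
        cfg = ClassifierConfig(n_iter=20, test_frac=0.5, n_perm=30, runs_per_perm=2,
                               n_trees=25, seed=0)
        res = classify_familiarity_behavior(feats, cfg)
        assert res.mean_accuracy == 1.0
        assert res.p_value <= 1.0 / cfg.n_perm

    def test_null_chance_level_centered(self, rng):
        """Label-exchangeable features give a permutation null centered on
        50% (balanced subsampled classes)."""
        feats = self._features(rng, separable=False)
        cfg = ClassifierConfig(n_iter=10, test_frac=0.5, n_perm=100, runs_per_perm=5,
                               n_trees=10, seed=1)
        res = classify_familiarity_behavior(feats, cfg)
        assert abs(res.chance_level - 0.5) < 0.02

    def test_normalization_absorbs_per_bird_affine_rescaling(self, rng):
        feats = self._features(rng)
        scaled = feats.copy()
        for b, idx in scaled.groupby("bird_id").groups.items():
            c = 1.0 + rng.random() * 5
            d = rng.standard_normal() * 100
            for col in BEHAVIOR_FEATURES:
                scaled.loc[idx, col] = scaled.loc[idx, col] * c + d
        a = minmax_normalize_per_group(feats, BEHAVIOR_FEATURES, "bird_id")
        b = minmax_normalize_per_group(scaled, BEHAVIOR_FEATURES, "bird_id")
        for col in BEHAVIOR_FEATURES:
            np.testing.assert_allclose(a[col].to_numpy(), b[col].to_numpy(), atol=1e-10)


def test_null_features_accuracy_inside_null_band():
    """Generated data with no familiarity effect is classified at chance."""
    cfg = null_synth_config(123, n_days=1, n_blocks=8)
    feats = pd.concat(
        [
            behavioral_features(s.trials, s.responses, s.bird_id)
            for s in (gen_behavior_session(cfg, b) for b in range(6))
        ],
        ignore_index=True,
    )
    res = classify_familiarity_behavior(
        feats, ClassifierConfig(n_iter=15, n_perm=40, runs_per_perm=4, n_trees=15, seed=5)
    )
    assert res.mean_accuracy <= res.null_ci95
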