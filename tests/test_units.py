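"""Per-unit processing: QC, waveform classes, z-scored PSTHs, responsiveness
and response features."""

import numpy as np
import pandas as pd
import pytest

from callcode import QCThresholds, SynthConfig
from callcode.config import BROAD, NARROW
from callcode.synthgen import gen_spike_population
from callcode.units import (
    ZScoredPSTH,
    classify_waveform,
    is_responsive,
    isi_violation_index,
    presence_ratio,
    psth_zscore,
    qc_filter,
    response_features,
)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def _units(self, **overrides):
        base = {
            "unit_id": "u0",
            "amplitude_cutoff": 0.1,
            "presence_ratio": 0.95,
            "isi_violation_index": 0.05,
        }
        base.update(overrides)
        return pd.DataFrame([base])

    def test_boundary_presence_ratio_excluded(self):
        retained, report = qc_filter(self._units(presence_ratio=0.69))
        assert len(retained) == 0
        assert report["reasons"].iloc[0] == "presence_ratio"

    def test_all_passing_retained(self):
        retained, report = qc_filter(self._units())
        assert len(retained) == 1 and report["passed"].iloc[0]

    def test_missing_metric_excludes_with_reason(self):
        retained, report = qc_filter(self._units(amplitude_cutoff=np.nan))
        assert len(retained) == 0
        assert "amplitude_cutoff" in report["reasons"].iloc[0]

    def test_printed_isi_direction_available(self):
        thr = QCThresholds(isi_direction="greater")
        retained, _ = qc_filter(self._units(isi_violation_index=0.5), thr)
        assert len(retained) == 1

    def test_contaminated_units_filtered_exactly(self):
        """30% of units seeded with low presence ratio are exactly the ones
        removed."""
        cfg = SynthConfig(seed=0, n_narrow=12, n_broad=28, contamination_frac=0.3)
        sess = gen_spike_population(cfg, contamination_mode="presence")
        tab = pd.DataFrame([{"unit_id": u.unit_id, **u.qc} for u in sess.units])
        retained, _ = qc_filter(tab)
        assert len(retained) == 40 - 12
        assert set(tab["unit_id"]) - set(retained["unit_id"]) == set(
            sess.ground_truth["contaminated_units"]
        )

    def test_isi_contamination_fails_conventional_criterion(self):
        cfg = SynthConfig(seed=1, n_narrow=6, n_broad=0, contamination_frac=0.5,
                          n_trials_per_condition=20)
        sess = gen_spike_population(cfg, contamination_mode="isi")
        tab = pd.DataFrame([{"unit_id": u.unit_id, **u.qc} for u in sess.units])
        retained, _ = qc_filter(tab)
        assert len(retained) == 3

    def test_presence_ratio_definition(self):
        spikes = np.array([0.5, 1.5, 2.5, 3.5, 4.5])  # 5 of 10 one-second chunks
        assert presence_ratio(spikes, 10.0, n_chunks=10) == 0.5

    def test_isi_violation_index_zero_for_regular_train(self):
        spikes = np.arange(0, 100, 0.1)  # 100 ms ISIs, no violations
        assert isi_violation_index(spikes, 100.0) == 0.0


# ---------------------------------------------------------------------------
# waveform classification
# ---------------------------------------------------------------------------

class TestWaveformClass:
    def _waveform(self, trough_idx, peak_idx, n=60):
        w = np.zeros(n)
        w[trough_idx] = -1.0
        w[peak_idx] = 0.5
        return w

    def test_boundary_exactly_at_split_is_broad(self):
        # 7 samples at 20 kHz = 0.35 ms exactly
        res = classify_waveform(self._waveform(10, 17), sample_rate_khz=20.0)
        assert res.trough_to_peak_ms == pytest.approx(0.35)
        assert res.putative_class == BROAD

    def test_one_sample_under_split_is_narrow(self):
        res = classify_waveform(self._waveform(10, 16), sample_rate_khz=20.0)
        assert res.putative_class == NARROW

    def test_no_post_trough_peak_flagged(self):
        w = -np.linspace(0.0, 1.0, 50)  # monotonically decreasing to the end
        res = classify_waveform(w, sample_rate_khz=30.0)
        assert res.flagged and res.putative_class is None


# ---------------------------------------------------------------------------
# z-scored PSTH
# ---------------------------------------------------------------------------

def _psth_from_counts(baseline_pattern, window_pattern, n_trials=1, bin_ms=10.0):
    """Build a spike train whose per-bin counts follow the given patterns."""
    spikes = []
    onsets = np.arange(n_trials) * 10.0 + 5.0
    half = bin_ms / 2000.0  # place spikes mid-bin, away from edges
    for t0 in onsets:
        for i, c in enumerate(baseline_pattern):
            t = t0 - 0.4 + i * bin_ms / 1000.0 + half
            spikes += [t + 0.001 * k for k in range(int(c))]
        for i, c in enumerate(window_pattern):
            t = t0 + i * bin_ms / 1000.0 + half
            spikes += [t + 0.001 * k for k in range(int(c))]
    return np.sort(np.array(spikes)), onsets


class TestPSTHZscore:
    def test_formula_on_deterministic_counts(self):
        """Baseline bins alternating 0/1 spikes and a 2-spike window bin give
        z = (200 − 50) / 50 = 3 without smoothing."""
        baseline = [1, 0] * 20
        window = [2] * 40
        spikes, onsets = _psth_from_counts(baseline, window)
        z = psth_zscore(spikes, onsets, smoothing="none")
        assert z.baseline_mean_hz == pytest.approx(50.0)
        assert z.baseline_sd_hz == pytest.approx(50.0)
        post = z.time_bins_ms > 0
        np.testing.assert_allclose(z.z[post], 3.0)

    def test_rate_equal_to_baseline_mean_gives_zero_z(self):
        baseline = [1, 0] * 20
        window = [1, 0] * 20
        spikes, onsets = _psth_from_counts(baseline, window)
        z = psth_zscore(spikes, onsets, smoothing="none")
        assert z.z[z.time_bins_ms > 0].mean() == pytest.approx(0.0)

    def test_affine_invariance_by_spike_duplication(self):
        """Tripling every spike scales all rates by 3 and leaves z unchanged."""
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 60, 600))
        onsets = np.arange(1.0, 59.0, 1.2)
        z1 = psth_zscore(spikes, onsets)
        z3 = psth_zscore(np.sort(np.repeat(spikes, 3)), onsets)
        np.testing.assert_allclose(z1.z, z3.z, atol=1e-9)
        assert z3.baseline_mean_hz == pytest.approx(3 * z1.baseline_mean_hz)

    def test_zero_baseline_variance_flagged(self):
        spikes = np.array([100.0])
        onsets = np.array([50.0])
        z = psth_zscore(spikes, onsets, smoothing="none")
        assert z.flagged and np.all(np.isnan(z.z))

    def test_null_unit_mean_z_near_zero(self):
        """Homogeneous Poisson units have window z fluctuating around 0."""
        rng = np.random.default_rng(3)
        means = []
        for _ in range(60):
            spikes = np.sort(rng.uniform(0, 70, rng.poisson(9.5 * 70)))
            onsets = np.arange(1.0, 68.0, 1.2)
            z = psth_zscore(spikes, onsets)
            means.append(z.z[(z.time_bins_ms >= 0) & (z.time_bins_ms <= 400)].mean())
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(len(means))


# ---------------------------------------------------------------------------
# responsiveness + features
# ---------------------------------------------------------------------------

def _zpsth(z, bin_ms=10.0):
    z = np.asarray(z, dtype=float)
    centers = -400 + bin_ms / 2 + bin_ms * np.arange(z.size)
    return ZScoredPSTH(
        unit_id="u", condition="c", time_bins_ms=centers, rate_hz=z.copy(), z=z,
        baseline_mean_hz=10.0, baseline_sd_hz=1.0, bin_ms=bin_ms, smoothing="none",
        n_trials=10,
    )


class TestResponsiveness:
    def test_flat_series_not_responsive(self):
        assert not is_responsive(_zpsth(np.zeros(80)))

    @pytest.mark.parametrize(
        "t_ms,expected", [(395.0, True), (405.0, False), (-5.0, False)]
    )
    def test_single_excursion_window_boundaries(self, t_ms, expected):
        z = np.zeros(85)  # bins extend past the 400 ms window edge
        centers = -400 + 5.0 + 10.0 * np.arange(85)
        z[np.argmin(np.abs(centers - t_ms))] = 2.5
        assert is_responsive(_zpsth(z)) is expected

    def test_negative_deflection_counts(self):
        z = np.zeros(80)
        z[45] = -2.5
        assert is_responsive(_zpsth(z))


class TestResponseFeatures:
    def test_flat_zero(self):
        f = response_features(_zpsth(np.zeros(80)))
        assert (f.mean_z, f.max_z, f.response_duration_ms) == (0.0, 0.0, 0.0)

    def test_block_of_suprathreshold_bins(self):
        z = np.zeros(80)
        z[40:50] = 3.0  # bins covering 0-100 ms
        f = response_features(_zpsth(z))
        assert f.response_duration_ms == 100.0
        assert f.time_of_max_ms == 5.0  # earliest max bin center
        assert f.max_z == 3.0

    def test_brute_force_oracle_on_random_series(self, rng):
        """Features equal an explicit loop over window bins."""
        for _ in range(300):
            z = rng.standard_normal(80) * 2
            f = response_features(_zpsth(z))
            centers = np.arange(-400 + 5.0, 400, 10.0)
            sel = [(t, v) for t, v in zip(centers, z) if 0 <= t <= 400]
            best_t, best_v = max(sel, key=lambda p: (p[1], -p[0]))
            assert f.max_z == pytest.approx(best_v)
            assert f.time_of_max_ms == best_t
            assert f.mean_z == pytest.approx(np.mean([v for _, v in sel]))
            assert f.response_duration_ms == pytest.approx(
                10.0 * sum(v >= 2.0 for _, v in sel)
            )


def test_responsiveness_false_positive_rate_bounded():
    """On null units the ±2σ / any-bin rule fires at most at the rate implied
    by 40 independent bins; smoothing only lowers it."""
    rng = np.random.default_rng(9)
    hits = {"none": 0, "gaussian": 0}
    n_units = 150
    for _ in range(n_units):
        spikes = np.sort(rng.uniform(0, 70, rng.poisson(9.5 * 70)))
        onsets = np.arange(1.0, 68.0, 1.2)
        for smoothing in hits:
            z = psth_zscore(spikes, onsets, smoothing=smoothing)
            hits[smoothing] += is_responsive(z)
    p_bin = 0.0455
    bound = 1 - (1 - p_bin) ** 40
    sem = np.sqrt(bound * (1 - bound) / n_units)
    assert hits["none"] / n_units <= bound + 3 * sem + 0.05
    assert hits["gaussian"] <= hits["none"]
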