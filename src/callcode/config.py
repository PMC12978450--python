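"""Configuration objects for the synthetic-data generator and pipeline runs.

All parameters are plain scalars or small string-keyed dictionaries so that a
full run configuration round-trips through YAML unchanged.  Familiarity levels
are keyed ``"familiar"`` / ``"unfamiliar"`` and waveform classes ``"narrow"``
(putative interneurons) / ``"broad"`` (putative projection neurons).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

FAMILIAR = "familiar"
UNFAMILIAR = "unfamiliar"
FAMILIARITY_LEVELS = (FAMILIAR, UNFAMILIAR)

NARROW = "narrow"
BROAD = "broad"
WAVEFORM_CLASSES = (NARROW, BROAD)


def _fam_dict(familiar: float, unfamiliar: float) -> dict[str, float]:
    return {FAMILIAR: familiar, UNFAMILIAR: unfamiliar}


@dataclass
class SynthConfig:
    """Parameters of the synthetic playback experiment.

    Defaults emulate the study conditions: 1 s inter-playback silence, 20
    blocks of 6 repetitions of each playback per session, 4 daily sessions for
    behavior, at least 48 trials per condition for head-fixed recordings,
    response probabilities/latencies biased toward the familiar caller, and
    two waveform classes (narrow ~0.20 ms trough-to-peak firing near 9.5 Hz,
    broad ~0.52 ms near 1.9 Hz) whose playback-evoked response is an early
    transient (first ~50 ms) plus a slowly decaying sustained component that
    outlasts stimulus offset.  The narrow-class evoked gain is
    familiarity-dependent; broad-class responses lag narrow ones by
    ``coupling_lag_ms`` when coupling is enabled.
    """

    seed: int = 0

    # --- behavioral playback schedule ---
    n_birds: int = 9
    n_unfamiliar_per_bird: int = 4  # plus exactly 1 familiar playback per bird
    n_days: int = 4
    n_blocks: int = 20
    reps_per_block: int = 6
    inter_playback_gap_s: float = 1.0
    block_gap_s: float = 60.0
    playback_dur_ms: float = 150.0

    # --- behavioral response model ---
    resp_prob: dict[str, float] = field(default_factory=lambda: _fam_dict(0.117, 0.090))
    latency_mean_ms: dict[str, float] = field(default_factory=lambda: _fam_dict(306.0, 354.0))
    latency_sd_ms: dict[str, float] = field(default_factory=lambda: _fam_dict(246.0, 264.0))
    response_dur_ms: float = 120.0

    # --- spike population ---
    n_narrow: int = 20
    n_broad: int = 40
    n_trials_per_condition: int = 48
    baseline_rate_hz: dict[str, float] = field(
        default_factory=lambda: {NARROW: 9.5, BROAD: 1.9}
    )
    # evoked_gain[class][familiarity]: dimensionless multiplier on the
    # baseline rate at the peak of the evoked profile.
    evoked_gain: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            NARROW: _fam_dict(0.80, 0.65),
            BROAD: _fam_dict(1.6, 1.6),
        }
    )
    gain_jitter_sd: float = 0.25  # per-unit log-normal gain spread (log scale)
    # per-unit evoked-response onset delay (exponential mean, capped), giving
    # the population the broad spread of peak-response times seen in data;
    # 0 makes every unit respond at stimulus onset
    response_delay_mean_ms: float = 70.0
    response_delay_max_ms: float = 300.0
    transient_rise_ms: float = 12.0
    # sustained-component amplitude relative to the transient peak, per
    # class × familiarity
    sustain_frac: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            NARROW: _fam_dict(0.45, 0.45),
            BROAD: _fam_dict(0.45, 0.45),
        }
    )
    sustain_rise_ms: float = 30.0
    # sustained-component decay constant per class × familiarity: the narrow
    # class responds both more strongly and longer to familiar callers
    sustain_tau_ms: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            NARROW: _fam_dict(170.0, 139.0),
            BROAD: _fam_dict(150.0, 150.0),
        }
    )
    coupling: bool = True
    coupling_lag_ms: float = 20.0
    # latent per-stimulus "salience" tying behavioral responsivity to
    # narrow-class evoked gain (0 disables behavior-neural coupling)
    salience_sd: float = 0.0

    # --- waveforms and QC ---
    trough_to_peak_ms: dict[str, float] = field(
        default_factory=lambda: {NARROW: 0.20, BROAD: 0.52}
    )
    trough_to_peak_sd_ms: dict[str, float] = field(
        default_factory=lambda: {NARROW: 0.03, BROAD: 0.06}
    )
    waveform_sample_rate_khz: float = 30.0
    contamination_frac: float = 0.0  # fraction of units seeded to fail QC
    # absolute dead time; on by default (matching the 1.5 ms refractory
    # window of the violation index) so clean units satisfy the conventional
    # QC criterion deterministically (set 0 for pure Poisson)
    refractory_dead_time_ms: float = 1.5

    # --- synthetic call audio ---
    audio_sample_rate_hz: int = 44100
    clip_dur_ms: float = 150.0
    n_clips_per_cluster: int = 8
    cluster_f0_hz: tuple[float, ...] = (620.0, 980.0, 1450.0)
    # rendition-to-rendition jitter of f0/duration; stack calls are highly
    # stereotyped, and renditions must stay phase-coherent over the clip for
    # raw-waveform similarity to reflect cluster identity
    f0_jitter_frac: float = 0.0005
    n_harmonics: int = 8

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for level in FAMILIARITY_LEVELS:
            p = self.resp_prob[level]
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"resp_prob[{level}]={p} outside [0, 1]")
            if self.latency_sd_ms[level] <= 0:
                raise ValueError("latency_sd_ms must be > 0")
        for name in (
            "inter_playback_gap_s",
            "playback_dur_ms",
            "response_dur_ms",
            "clip_dur_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for cls in WAVEFORM_CLASSES:
            for level in FAMILIARITY_LEVELS:
                if self.sustain_tau_ms[cls][level] <= 0:
                    raise ValueError("sustain_tau_ms must be > 0")
        for cls in WAVEFORM_CLASSES:
            if self.baseline_rate_hz[cls] <= 0:
                raise ValueError("baseline rates must be > 0")
            for level in FAMILIARITY_LEVELS:
                if self.evoked_gain[cls][level] < 0:
                    raise ValueError("evoked gains must be >= 0")
        if not 0.0 <= self.contamination_frac <= 1.0:
            raise ValueError("contamination_frac outside [0, 1]")
        # the latency distribution must place appreciable mass inside the
        # inter-trial span, otherwise answered trials cannot be realized
        from scipy import stats

        span = self.trial_period_ms
        for level in FAMILIARITY_LEVELS:
            mu = self.latency_mean_ms[level]
            sd = self.latency_sd_ms[level]
            mass = stats.norm.cdf(span, mu, sd) - stats.norm.cdf(0.0, mu, sd)
            if mass < 0.01:
                raise ValueError(
                    f"latency distribution for {level!r} places <1% mass in "
                    f"the {span:.0f} ms inter-trial span"
                )

    # -- derived quantities ---------------------------------------------
    @property
    def trial_period_ms(self) -> float:
        """Playback duration plus the silent gap, i.e. onset-to-onset time."""
        return self.playback_dur_ms + 1000.0 * self.inter_playback_gap_s

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cluster_f0_hz"] = list(self.cluster_f0_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SynthConfig":
        d = dict(d)
        if "cluster_f0_hz" in d:
            d["cluster_f0_hz"] = tuple(d["cluster_f0_hz"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass
class QCThresholds:
    """Single-unit quality-control cutoffs.

    ``isi_direction`` selects whether the interspike-interval violation index
    must fall below (``"less"``, conventional) or above (``"greater"``) the
    threshold; both directions are provided because published criteria are
    stated inconsistently.
    """

    amplitude_cutoff_max: float = 0.5
    presence_ratio_min: float = 0.70
    isi_violation_threshold: float = 0.3
    isi_direction: str = "less"

    def __post_init__(self) -> None:
        if self.isi_direction not in ("less", "greater"):
            raise ValueError("isi_direction must be 'less' or 'greater'")


@dataclass
class ClassifierConfig:
    """Shared settings for the permutation-calibrated classifiers."""

    n_iter: int = 1000
    test_frac: float = 0.5
    n_perm: int = 1000
    runs_per_perm: int = 10
    n_trees: int = 100  # random forest only
    svm_c: float = 1.0  # linear SVM only
    seed: int = 0
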