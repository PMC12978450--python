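"""Seeded synthetic playback experiments with known ground truth.

This module fabricates the three kinds of raw material the analysis consumes:

* behavioral playback sessions — pseudo-randomized blocks of familiar and
  unfamiliar call playbacks at 1 s inter-playback silence, answered with
  familiarity-dependent probability and truncated-normal latency;
* head-fixed recording sessions — populations of narrow- and broad-waveform
  units firing as inhomogeneous Poisson processes whose playback-evoked rate
  is an early transient (~first 50 ms) plus an exponentially decaying
  sustained component outlasting stimulus offset, with familiarity-dependent
  gain for the narrow class and an optional narrow→broad coupling lag;
* harmonic-stack call clips with imposed cluster structure.

Everything is driven by a :class:`~callcode.config.SynthConfig`; identical
configurations (including the seed) reproduce outputs exactly.  Ground-truth
effect sizes are recorded on each generated object so recovery tests can
compare estimates against the generating parameters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    BROAD,
    FAMILIAR,
    NARROW,
    UNFAMILIAR,
    SynthConfig,
)

RATE_GRID_MS = 1.0  # resolution of the latent rate used for spike generation
PROFILE_SPAN_MS = 1000.0  # evoked profile support; the tail is negligible after
DAY_GAP_S = 600.0

__all__ = [
    "AudioClip",
    "BehaviorSession",
    "RecordingSession",
    "UnitRecord",
    "evoked_profile",
    "gen_behavior_session",
    "gen_call_audio",
    "gen_paired_dataset",
    "gen_spike_population",
    "make_waveform",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSession:
    """One bird's playback sessions (all days concatenated on one time axis)."""

    bird_id: str
    trials: pd.DataFrame  # trial_id, stimulus_id, familiarity, caller_sex, day, onset_s, offset_s
    responses: pd.DataFrame  # trial_id, onset_s, offset_s
    ground_truth: dict


@dataclass
class UnitRecord:
    """One sorted unit: spike times, mean waveform and QC metrics."""

    unit_id: str
    session_id: str
    spike_times_s: np.ndarray
    mean_waveform: np.ndarray
    waveform_sample_rate_khz: float
    qc: dict
    class_truth: str
    trough_to_peak_ms_truth: float
    gain_truth: dict = field(default_factory=dict)


@dataclass
class RecordingSession:
    session_id: str
    bird_id: str
    trials: pd.DataFrame
    units: list[UnitRecord]
    ground_truth: dict


@dataclass
class AudioClip:
    samples: np.ndarray
    sample_rate_hz: int
    stimulus_id: str
    familiarity_role: str = "both"
    cluster_truth: int = -1


def _rng(config: SynthConfig, stream: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-(stream, index) generator derived from the config seed."""
    entropy = (int(config.seed), zlib.crc32(stream.encode()), int(index))
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# playback schedule
# ---------------------------------------------------------------------------

def _schedule(
    stimuli: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
    n_days: int,
    n_blocks: int,
    reps_per_block: int,
) -> pd.DataFrame:
    """Pseudo-random block schedule: each block holds ``reps_per_block``
    repetitions of every stimulus in shuffled order, blocks separated by a
    silent pause, playbacks by the inter-playback gap."""
    period_s = config.trial_period_ms / 1000.0
    dur_s = config.playback_dur_ms / 1000.0
    rows = []
    t = 0.0
    trial_no = 0
    stim_idx = np.repeat(np.arange(len(stimuli)), reps_per_block)
    for day in range(n_days):
        for _ in range(n_blocks):
            order = rng.permutation(stim_idx)
            for k in order:
                stim = stimuli.iloc[int(k)]
                rows.append(
                    {
                        "trial_id": f"t{trial_no:05d}",
                        "stimulus_id": stim["stimulus_id"],
                        "familiarity": stim["familiarity"],
                        "caller_sex": stim.get("caller_sex", "female"),
                        "day": day,
                        "onset_s": t,
                        "offset_s": t + dur_s,
                    }
                )
                trial_no += 1
                t += period_s
            t += config.block_gap_s
        t += DAY_GAP_S
    return pd.DataFrame(rows)


def _bird_stimuli(config: SynthConfig, bird: int) -> pd.DataFrame:
    """One familiar playback plus ``n_unfamiliar_per_bird`` unfamiliar ones."""
    rows = [
        {
            "stimulus_id": f"b{bird}_fam0",
            "familiarity": FAMILIAR,
            "caller_sex": "female",
        }
    ]
    for j in range(config.n_unfamiliar_per_bird):
        rows.append(
            {
                "stimulus_id": f"b{bird}_unf{j}",
                "familiarity": UNFAMILIAR,
                "caller_sex": "female" if j % 2 == 0 else "male",
            }
        )
    return pd.DataFrame(rows)


def _truncnorm_latency(
    mu: float, sd: float, span_ms: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    a, b = (0.0 - mu) / sd, (span_ms - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def gen_behavior_session(
    config: SynthConfig,
    bird: int = 0,
    salience: dict[str, float] | None = None,
) -> BehaviorSession:
    """Simulate one bird's playback sessions and its call responses.

    Each trial is answered independently with the familiarity level's response
    probability (optionally modulated by a per-stimulus ``salience`` factor);
    answered trials receive a first-response latency drawn from a normal
    distribution truncated to the onset-to-onset span.  Responses that would
    collide with the next playback are truncated at its onset, never dropped.
    """
    config.validate()
    rng = _rng(config, "behavior", bird)
    stimuli = _bird_stimuli(config, bird)
    trials = _schedule(
        stimuli, config, rng, config.n_days, config.n_blocks, config.reps_per_block
    )
    span_ms = config.trial_period_ms
    sal = salience or {}

    resp_rows = []
    for level in (FAMILIAR, UNFAMILIAR):
        mask = trials["familiarity"] == level
        idx = np.flatnonzero(mask.to_numpy())
        p = np.array(
            [
                min(1.0, config.resp_prob[level] * sal.get(s, 1.0))
                for s in trials.loc[mask, "stimulus_id"]
            ]
        )
        answered = idx[rng.random(idx.size) < p]
        lat = _truncnorm_latency(
            config.latency_mean_ms[level],
            config.latency_sd_ms[level],
            span_ms,
            answered.size,
            rng,
        )
        onset = trials["onset_s"].to_numpy()[answered] + lat / 1000.0
        next_onset = trials["onset_s"].to_numpy()[answered] + span_ms / 1000.0
        offset = np.minimum(onset + config.response_dur_ms / 1000.0, next_onset)
        for i, o, f in zip(answered, onset, offset):
            resp_rows.append(
                {"trial_id": trials["trial_id"].iloc[int(i)], "onset_s": o, "offset_s": f}
            )
    responses = (
        pd.DataFrame(resp_rows, columns=["trial_id", "onset_s", "offset_s"])
        .sort_values("onset_s")
        .reset_index(drop=True)
    )
    truth = {
        "resp_prob": dict(config.resp_prob),
        "latency_mean_ms": dict(config.latency_mean_ms),
        "latency_sd_ms": dict(config.latency_sd_ms),
        "salience": dict(sal),
    }
    return BehaviorSession(f"bird{bird}", trials, responses, truth)


# ---------------------------------------------------------------------------
# spike population
# ---------------------------------------------------------------------------

def evoked_profile(
    config: SynthConfig,
    sustain_tau_ms: float | None = None,
    sustain_frac: float | None = None,
    dt_ms: float = RATE_GRID_MS,
) -> np.ndarray:
    """Unit-peak evoked rate profile on a ``dt_ms`` grid from playback onset.

    An alpha-function transient ``(t/τ_r)·exp(1 − t/τ_r)`` (peak 1 at
    ``transient_rise_ms``, essentially over by ~50 ms) plus a sustained
    component of amplitude ``sustain_frac`` that rises with time constant
    ``sustain_rise_ms`` and decays with ``sustain_tau_ms``, persisting past
    stimulus offset.
    """
    if sustain_tau_ms is None:
        sustain_tau_ms = config.sustain_tau_ms[NARROW][FAMILIAR]
    if sustain_frac is None:
        sustain_frac = config.sustain_frac[NARROW][FAMILIAR]
    t = np.arange(0.0, PROFILE_SPAN_MS, dt_ms)
    tr = config.transient_rise_ms
    transient = (t / tr) * np.exp(1.0 - t / tr)
    sustain = (
        sustain_frac
        * (1.0 - np.exp(-t / config.sustain_rise_ms))
        * np.exp(-t / sustain_tau_ms)
    )
    prof = transient + sustain
    if np.any(prof < 0):
        raise ValueError("evoked profile produced negative rates")
    return prof


def make_waveform(
    ttp_ms: float, sample_rate_khz: float, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Biphasic mean waveform: unit-amplitude trough followed by a smaller
    positive peak ``ttp_ms`` later, on a 2.5 ms support."""
    dt = 1.0 / sample_rate_khz
    t = np.arange(0.0, 2.5, dt)
    t0 = 0.8
    trough_w = 0.07 + 0.08 * ttp_ms
    peak_w = 0.10 + 0.35 * ttp_ms
    w = -np.exp(-0.5 * ((t - t0) / trough_w) ** 2) + 0.55 * np.exp(
        -0.5 * ((t - t0 - ttp_ms) / peak_w) ** 2
    )
    if rng is not None:
        w = w + 0.005 * rng.standard_normal(t.size)
    return w


def _poisson_spikes(
    rate_hz: np.ndarray, dt_s: float, rng: np.random.Generator, dead_time_s: float
) -> np.ndarray:
    if np.any(rate_hz < 0):
        raise ValueError("negative instantaneous rate")
    counts = rng.poisson(rate_hz * dt_s)
    idx = np.repeat(np.arange(counts.size), counts)
    times = (idx + rng.random(idx.size)) * dt_s
    times.sort()
    if dead_time_s > 0 and times.size > 1:
        keep = np.ones(times.size, dtype=bool)
        last = times[0]
        for i in range(1, times.size):
            if times[i] - last < dead_time_s:
                keep[i] = False
            else:
                last = times[i]
        times = times[keep]
    return times


def gen_spike_population(
    config: SynthConfig,
    session: int = 0,
    bird_id: str | None = None,
    stimuli: pd.DataFrame | None = None,
    salience: dict[str, float] | None = None,
    contamination_mode: str = "presence",
) -> RecordingSession:
    """Simulate one head-fixed recording session.

    Trials interleave all stimuli pseudo-randomly (``n_trials_per_condition``
    repetitions each, 1 s silent gap).  Every unit is an inhomogeneous Poisson
    process: class baseline rate plus, at each playback onset, the evoked
    profile scaled by ``baseline × evoked_gain[class][familiarity]`` and the
    unit's log-normal gain jitter.  Broad-class evoked responses are the
    narrow-class profile delayed by ``coupling_lag_ms`` when coupling is on.
    A ``contamination_frac`` of units is seeded to fail quality control via
    ``contamination_mode`` ('presence', 'amplitude' or 'isi').
    """
    config.validate()
    rng = _rng(config, "spikes", session)
    if stimuli is None:
        stimuli = pd.DataFrame(
            {
                "stimulus_id": [f"s{session}_fam", f"s{session}_unf"],
                "familiarity": [FAMILIAR, UNFAMILIAR],
            }
        )
    trials = _schedule(stimuli, config, rng, 1, 1, config.n_trials_per_condition)
    dur_s = trials["offset_s"].iloc[-1] + 2.0
    dt_s = RATE_GRID_MS / 1000.0
    n_bins = int(np.ceil(dur_s / dt_s))
    # broad-class evoked responses mirror the narrow-class profile (delayed by
    # the coupling lag) when coupling is enabled, else use their own decay
    profiles = {}
    for cls in (NARROW, BROAD):
        src = NARROW if (cls == BROAD and config.coupling) else cls
        for level in (FAMILIAR, UNFAMILIAR):
            profiles[(cls, level)] = evoked_profile(
                config,
                config.sustain_tau_ms[src][level],
                config.sustain_frac[src][level],
            )
    sal = salience or {}

    onset_bins = np.round(trials["onset_s"].to_numpy() / dt_s).astype(int)
    lag_bins = int(round(config.coupling_lag_ms / RATE_GRID_MS))

    classes = [NARROW] * config.n_narrow + [BROAD] * config.n_broad
    n_units = len(classes)
    n_contam = int(round(config.contamination_frac * n_units))
    contam = np.zeros(n_units, dtype=bool)
    if n_contam:
        contam[rng.choice(n_units, size=n_contam, replace=False)] = True

    units: list[UnitRecord] = []
    sid = f"sess{session}"
    for u, cls in enumerate(classes):
        base = config.baseline_rate_hz[cls]
        jitter = float(np.exp(config.gain_jitter_sd * rng.standard_normal()))
        if config.response_delay_mean_ms > 0:
            delay_bins = int(
                round(
                    min(
                        rng.exponential(config.response_delay_mean_ms),
                        config.response_delay_max_ms,
                    )
                    / RATE_GRID_MS
                )
            )
        else:
            delay_bins = 0
        rate = np.full(n_bins, base)
        for b, stim, level in zip(
            onset_bins, trials["stimulus_id"], trials["familiarity"]
        ):
            g = config.evoked_gain[cls][level] * jitter
            if cls == NARROW and sal:
                g *= sal.get(stim, 1.0)
            prof = profiles[(cls, level)]
            start = b + delay_bins + (lag_bins if (cls == BROAD and config.coupling) else 0)
            stop = min(start + prof.size, n_bins)
            if stop > start:
                rate[start:stop] += base * g * prof[: stop - start]
        spikes = _poisson_spikes(
            rate, dt_s, rng, config.refractory_dead_time_ms / 1000.0
        )
        ttp = float(
            np.clip(
                rng.normal(
                    config.trough_to_peak_ms[cls], config.trough_to_peak_sd_ms[cls]
                ),
                0.06,
                1.2,
            )
        )
        if contam[u]:
            if contamination_mode == "presence":
                # silence ~35% of session chunks => presence ratio <= 0.65
                n_chunks = 100
                edges = np.linspace(0.0, dur_s, n_chunks + 1)
                bad = rng.choice(n_chunks, size=35, replace=False)
                keep = np.ones(spikes.size, dtype=bool)
                for c in bad:
                    keep &= ~((spikes >= edges[c]) & (spikes < edges[c + 1]))
                spikes = spikes[keep]
            elif contamination_mode == "isi":
                doublets = spikes + rng.uniform(0.0002, 0.0012, spikes.size)
                spikes = np.sort(np.concatenate([spikes, doublets]))
            elif contamination_mode != "amplitude":
                raise ValueError(f"unknown contamination_mode {contamination_mode!r}")
        from .units import isi_violation_index, presence_ratio  # local: avoid cycle

        if contam[u] and contamination_mode == "amplitude":
            amp_cut = float(rng.uniform(0.55, 0.75))
        else:
            amp_cut = float(rng.uniform(0.01, 0.2))
        qc = {
            "presence_ratio": presence_ratio(spikes, dur_s),
            "isi_violation_index": isi_violation_index(spikes, dur_s),
            "amplitude_cutoff": amp_cut,
        }
        units.append(
            UnitRecord(
                unit_id=f"{sid}_u{u:03d}",
                session_id=sid,
                spike_times_s=spikes,
                mean_waveform=make_waveform(
                    ttp, config.waveform_sample_rate_khz, rng
                ),
                waveform_sample_rate_khz=config.waveform_sample_rate_khz,
                qc=qc,
                class_truth=cls,
                trough_to_peak_ms_truth=ttp,
                gain_truth={
                    level: config.evoked_gain[cls][level] * jitter
                    for level in (FAMILIAR, UNFAMILIAR)
                },
            )
        )
    truth = {
        "evoked_gain": {c: dict(v) for c, v in config.evoked_gain.items()},
        "coupling_lag_ms": config.coupling_lag_ms if config.coupling else None,
        "salience": dict(sal),
        "contaminated_units": [units[i].unit_id for i in np.flatnonzero(contam)],
    }
    return RecordingSession(sid, bird_id or f"bird{session}", trials, units, truth)


def gen_paired_dataset(
    config: SynthConfig, n_birds: int | None = None
) -> tuple[list[BehaviorSession], list[RecordingSession]]:
    """Behavior and recording sessions for the same birds and stimuli.

    When ``config.salience_sd > 0`` each stimulus receives a latent log-normal
    salience that multiplies both the behavioral response probability and the
    narrow-class evoked gain, installing a ground-truth positive coupling
    between behavioral responsivity and interneuron drive.
    """
    n_birds = config.n_birds if n_birds is None else n_birds
    behavior, recordings = [], []
    for b in range(n_birds):
        stimuli = _bird_stimuli(config, b)
        rng = _rng(config, "salience", b)
        if config.salience_sd > 0:
            sal = {
                s: float(np.exp(config.salience_sd * rng.standard_normal()))
                for s in stimuli["stimulus_id"]
            }
        else:
            sal = {}
        behavior.append(gen_behavior_session(config, b, salience=sal))
        recordings.append(
            gen_spike_population(
                config, session=b, bird_id=f"bird{b}", stimuli=stimuli, salience=sal
            )
        )
    return behavior, recordings


# ---------------------------------------------------------------------------
# call audio
# ---------------------------------------------------------------------------

def gen_call_audio(config: SynthConfig, n_clusters: int = 2) -> list[AudioClip]:
    """Harmonic-stack call clips with ``n_clusters`` acoustic clusters.

    Clusters differ in fundamental frequency and duration; within-cluster
    clips jitter both by ``f0_jitter_frac``.  With zero jitter all clips of a
    cluster are identical.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(config.cluster_f0_hz):
        raise ValueError("not enough cluster fundamentals configured")
    rng = _rng(config, "audio")
    sr = config.audio_sample_rate_hz
    clips = []
    for c in range(n_clusters):
        f0_c = config.cluster_f0_hz[c]
        dur_c = config.clip_dur_ms * (1.0 + 0.15 * c)
        for j in range(config.n_clips_per_cluster):
            jf = config.f0_jitter_frac
            f0 = f0_c * (1.0 + jf * rng.uniform(-1, 1))
            dur_ms = dur_c * (1.0 + jf * rng.uniform(-1, 1))
            n = int(round(dur_ms / 1000.0 * sr))
            t = np.arange(n) / sr
            x = np.zeros(n)
            for h in range(1, config.n_harmonics + 1):
                x += (1.0 / h) * np.sin(2 * np.pi * h * f0 * t)
            # attack-decay envelope typical of short harmonic calls
            env = np.minimum(t / 0.01, 1.0) * np.exp(-t / (0.6 * dur_ms / 1000.0))
            x *= env
            x *= 0.9 / np.max(np.abs(x))
            clips.append(
                AudioClip(
                    samples=x,
                    sample_rate_hz=sr,
                    stimulus_id=f"clip_c{c}_{j}",
                    cluster_truth=c,
                )
            )
    return clips
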