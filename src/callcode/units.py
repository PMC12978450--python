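"""Per-unit spike-train processing.

Quality-control filtering, waveform-based cell-class assignment (narrow
putative interneurons vs broad putative projection neurons, split at 0.35 ms
trough-to-peak), z-scored peri-stimulus time histograms, ±2 SD responsiveness
detection, and peri-stimulus response-feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

from .config import BROAD, NARROW, QCThresholds

NARROW_BROAD_SPLIT_MS = 0.35
RESPONSE_WINDOW_MS = (0.0, 400.0)

__all__ = [
    "ResponseFeatures",
    "ZScoredPSTH",
    "amplitude_cutoff",
    "classify_waveform",
    "is_responsive",
    "isi_violation_index",
    "presence_ratio",
    "psth_zscore",
    "qc_filter",
    "response_features",
]


# ---------------------------------------------------------------------------
# quality-control metrics
# ---------------------------------------------------------------------------

def presence_ratio(spike_times_s: np.ndarray, duration_s: float, n_chunks: int = 100) -> float:
    """Fraction of equal session chunks containing at least one spike."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    spikes = np.asarray(spike_times_s)
    counts, _ = np.histogram(spikes, bins=n_chunks, range=(0.0, duration_s))
    return float(np.mean(counts > 0))


def isi_violation_index(
    spike_times_s: np.ndarray, duration_s: float, refractory_ms: float = 1.5,
    censored_ms: float = 0.0,
) -> float:
    """Refractory-period violation rate ratio.

    Ratio of the observed rate of inter-spike intervals shorter than the
    refractory period to the rate expected from an independent contaminating
    process at the unit's overall rate (Hill-style contamination index).
    Returns 0 for fewer than two spikes.
    """
    spikes = np.asarray(spike_times_s)
    n = spikes.size
    if n < 2:
        return 0.0
    isis = np.diff(spikes)
    n_viol = int(np.sum(isis < refractory_ms / 1000.0))
    viol_window_s = 2.0 * (refractory_ms - censored_ms) / 1000.0 * n
    total_rate = n / duration_s
    expected = viol_window_s * total_rate
    if expected <= 0:
        return 0.0
    return float(n_viol / expected)


def amplitude_cutoff(amplitudes: np.ndarray, n_bins: int = 100, smooth_sigma: int = 3) -> float:
    """Estimated fraction of missed spikes from the amplitude histogram.

    Mirrors the histogram of spike amplitudes about its mode and reports the
    tail mass below the detection floor implied by the truncated low side.
    Capped at 0.5 (a symmetric distribution cut at its mode).
    """
    amps = np.asarray(amplitudes, dtype=float)
    if amps.size < 10:
        return np.nan
    h, edges = np.histogram(amps, bins=n_bins, density=True)
    h = gaussian_filter1d(h.astype(float), smooth_sigma)
    peak = int(np.argmax(h))
    # index on the high side where the density falls to the truncated low edge
    above = np.flatnonzero(h[peak:] < h[0])
    if above.size == 0:
        return 0.5
    g = peak + int(above[0])
    bin_w = edges[1] - edges[0]
    fraction = float(np.sum(h[g:]) * bin_w)
    return min(fraction, 0.5)


def qc_filter(
    units: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a units table on QC metrics.

    Expects columns ``amplitude_cutoff``, ``presence_ratio`` and
    ``isi_violation_index``; missing (NaN) metrics exclude the unit.  Returns
    ``(retained, report)`` where the report has one row per input unit with a
    ``passed`` flag and a comma-separated ``reasons`` column.
    """
    thr = thresholds or QCThresholds()
    reasons = []
    for _, row in units.iterrows():
        why = []
        amp = row.get("amplitude_cutoff", np.nan)
        pres = row.get("presence_ratio", np.nan)
        isi = row.get("isi_violation_index", np.nan)
        if not amp < thr.amplitude_cutoff_max:  # NaN fails too
            why.append("amplitude_cutoff")
        if not pres > thr.presence_ratio_min:
            why.append("presence_ratio")
        ok_isi = (
            isi < thr.isi_violation_threshold
            if thr.isi_direction == "less"
            else isi > thr.isi_violation_threshold
        )
        if not ok_isi:
            why.append("isi_violation_index")
        reasons.append(",".join(why))
    report = units[["unit_id"]].copy() if "unit_id" in units else pd.DataFrame(index=units.index)
    report["passed"] = [r == "" for r in reasons]
    report["reasons"] = reasons
    retained = units.loc[np.asarray(report["passed"]), :].reset_index(drop=True)
    return retained, report.reset_index(drop=True)


# ---------------------------------------------------------------------------
# waveform classification
# ---------------------------------------------------------------------------

@dataclass
class WaveformClass:
    trough_to_peak_ms: float
    putative_class: str | None
    flagged: bool = False


def classify_waveform(
    mean_waveform: np.ndarray, sample_rate_khz: float,
    split_ms: float = NARROW_BROAD_SPLIT_MS,
) -> WaveformClass:
    """Trough-to-peak duration and narrow/broad class of a mean waveform.

    Duration runs from the global minimum (trough) to the subsequent global
    maximum.  Units at exactly the split are classed broad.  A waveform whose
    trough is the last sample, or with no positive-going deflection after the
    trough, is flagged unclassifiable.
    """
    w = np.asarray(mean_waveform, dtype=float)
    trough = int(np.argmin(w))
    if trough >= w.size - 1:
        return WaveformClass(np.nan, None, flagged=True)
    after = w[trough + 1 :]
    peak = trough + 1 + int(np.argmax(after))
    if w[peak] <= w[trough]:
        return WaveformClass(np.nan, None, flagged=True)
    ttp_ms = (peak - trough) / sample_rate_khz
    cls = NARROW if ttp_ms < split_ms else BROAD
    return WaveformClass(float(ttp_ms), cls)


# ---------------------------------------------------------------------------
# z-scored PSTH
# ---------------------------------------------------------------------------

@dataclass
class ZScoredPSTH:
    """Trial-averaged, smoothed, baseline-z-scored firing rate of one unit.

    ``z = (rate − baseline mean) / baseline SD`` per bin, with the baseline
    statistics taken over the pre-onset ``baseline_window`` bins of the same
    trial-averaged series.
    """

    unit_id: str
    condition: str
    time_bins_ms: np.ndarray  # bin centers relative to playback onset
    rate_hz: np.ndarray
    z: np.ndarray
    baseline_mean_hz: float
    baseline_sd_hz: float
    bin_ms: float
    smoothing: str
    n_trials: int
    flagged: bool = False  # zero baseline variance: z undefined


def _smooth(rate: np.ndarray, bin_ms: float, smoothing: str) -> np.ndarray:
    if smoothing == "gaussian":
        return gaussian_filter1d(rate, sigma=3.0, mode="nearest")
    if smoothing == "savgol":
        win = max(3, int(round(51.0 / bin_ms)) | 1)
        return savgol_filter(rate, window_length=win, polyorder=1)
    if smoothing in (None, "none"):
        return rate
    raise ValueError(f"unknown smoothing {smoothing!r}")


def _trial_rate(
    spikes: np.ndarray, onsets: np.ndarray, edges: np.ndarray, bin_ms: float,
    smoothing: str,
) -> np.ndarray:
    lo, hi = edges[0], edges[-1]
    counts = np.zeros(edges.size - 1)
    for t0 in onsets:
        rel = (spikes - t0) * 1000.0
        sel = rel[(rel >= lo) & (rel < hi)]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / onsets.size / (bin_ms / 1000.0)
    return _smooth(rate, bin_ms, smoothing)


def psth_zscore(
    spike_times_s: np.ndarray,
    trial_onsets_s: np.ndarray,
    *,
    unit_id: str = "",
    condition: str = "",
    bin_ms: float = 10.0,
    window_ms: tuple[float, float] = (-400.0, 400.0),
    baseline_window_ms: tuple[float, float] = (-400.0, 0.0),
    smoothing: str = "gaussian",
    baseline_onsets_s: np.ndarray | None = None,
    reference_n: int | None = None,
) -> ZScoredPSTH:
    """Peri-stimulus z-scored firing rate aligned to the given onsets.

    The default 10 ms bins are smoothed by Gaussian convolution (kernel width
    3 bins); 1 ms display-resolution series use a 51 ms window, order-1
    Savitzky-Golay filter instead (``smoothing="savgol"``).  Pass only the
    trials to include — e.g. response-free trials of one condition.

    ``baseline_onsets_s`` lets the baseline statistics come from a larger
    trial set than the condition being averaged (e.g. all of the unit's
    response-free trials): a unit has one resting state, and sharing its
    baseline estimate across conditions removes spurious between-condition
    scale differences caused by independently estimated baseline SDs.  The
    baseline SD is rescaled to the noise level of a ``reference_n``-trial
    average (default: this condition's trial count); conditions meant to be
    compared should share one reference so their z values live on a common
    scale even when their trial counts differ.
    """
    onsets = np.asarray(trial_onsets_s, dtype=float)
    if onsets.size == 0:
        raise ValueError("at least one trial required")
    lo, hi = window_ms
    if not (baseline_window_ms[0] >= lo and baseline_window_ms[1] <= hi):
        raise ValueError("baseline window must lie inside the PSTH window")
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    spikes = np.asarray(spike_times_s)
    rate = _trial_rate(spikes, onsets, edges, bin_ms, smoothing)
    base = (centers >= baseline_window_ms[0]) & (centers < baseline_window_ms[1])
    n_ref = int(reference_n) if reference_n else onsets.size
    if baseline_onsets_s is not None and len(baseline_onsets_s) > 0:
        base_onsets = np.asarray(baseline_onsets_s, dtype=float)
        base_rate = _trial_rate(spikes, base_onsets, edges, bin_ms, smoothing)
        # the SD of an m-trial average understates an n-trial average's
        # noise by sqrt(n/m); rescale to the reference trial count
        scale = np.sqrt(base_onsets.size / n_ref)
    else:
        base_rate = rate
        scale = np.sqrt(onsets.size / n_ref)
    mu = float(np.mean(base_rate[base]))
    sd = float(np.std(base_rate[base]) * scale)
    flagged = sd <= 0
    z = np.full_like(rate, np.nan) if flagged else (rate - mu) / sd
    return ZScoredPSTH(
        unit_id=unit_id,
        condition=condition,
        time_bins_ms=centers,
        rate_hz=rate,
        z=z,
        baseline_mean_hz=mu,
        baseline_sd_hz=sd,
        bin_ms=bin_ms,
        smoothing=smoothing,
        n_trials=int(onsets.size),
        flagged=flagged,
    )


def response_free_onsets(
    trials: pd.DataFrame, responses: pd.DataFrame | None, condition: str
) -> np.ndarray:
    """Onsets of one condition's trials that received no vocal response."""
    sel = trials[trials["familiarity"] == condition]
    if responses is None or len(responses) == 0:
        return sel["onset_s"].to_numpy()
    answered = set(responses["trial_id"])
    keep = ~sel["trial_id"].isin(answered)
    return sel.loc[keep, "onset_s"].to_numpy()


# ---------------------------------------------------------------------------
# responsiveness and response features
# ---------------------------------------------------------------------------

def is_responsive(
    zpsth: ZScoredPSTH,
    window_ms: tuple[float, float] = RESPONSE_WINDOW_MS,
    threshold_sd: float = 2.0,
) -> bool:
    """True iff any bin inside the window deviates ``±threshold_sd`` from baseline."""
    if zpsth.flagged:
        raise ValueError("z undefined (zero baseline variance)")
    m = (zpsth.time_bins_ms >= window_ms[0]) & (zpsth.time_bins_ms <= window_ms[1])
    return bool(np.any(np.abs(zpsth.z[m]) >= threshold_sd))


@dataclass
class ResponseFeatures:
    unit_id: str
    condition: str
    mean_z: float
    max_z: float
    time_of_max_ms: float
    response_duration_ms: float
    responsive: bool


def response_features(
    zpsth: ZScoredPSTH,
    window_ms: tuple[float, float] = RESPONSE_WINDOW_MS,
    threshold_sd: float = 2.0,
) -> ResponseFeatures:
    """Window-mean z, max z, time of max (earliest bin on ties) and response
    duration — total (not necessarily contiguous) time with z ≥ 2 inside the
    window."""
    if zpsth.flagged:
        raise ValueError("z undefined (zero baseline variance)")
    m = (zpsth.time_bins_ms >= window_ms[0]) & (zpsth.time_bins_ms <= window_ms[1])
    zwin = zpsth.z[m]
    twin = zpsth.time_bins_ms[m]
    imax = int(np.argmax(zwin))
    duration = float(np.sum(zwin >= threshold_sd) * zpsth.bin_ms)
    return ResponseFeatures(
        unit_id=zpsth.unit_id,
        condition=zpsth.condition,
        mean_z=float(np.mean(zwin)),
        max_z=float(zwin[imax]),
        time_of_max_ms=float(twin[imax]),
        response_duration_ms=duration,
        responsive=bool(np.any(np.abs(zwin) >= threshold_sd)),
    )
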