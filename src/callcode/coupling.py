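"""Behavior–neural coupling and interneuron→projection-neuron timing.

Correlates per-stimulus behavioral response features with interneuron
response features (Pearson with Bonferroni correction over the feature
grid, Spearman fallback when normality fails), and quantifies the temporal
lead of narrow-waveform over broad-waveform units by normalized
cross-correlation of their peri-stimulus firing rates.

Lag sign convention: a *negative* best lag means the first (interneuron)
signal leads the second (projection-neuron) signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationTable",
    "CrossCorrResult",
    "behavior_neural_correlation",
    "best_lag",
    "interneuron_pn_lags",
    "normalized_crosscorr",
]

BEHAVIOR_COLS = ["peak_response_prob", "response_latency_ms", "latency_variability_ms"]
NEURAL_COLS = ["mean_z", "max_z", "response_duration_ms"]


# ---------------------------------------------------------------------------
# behavior x neural correlation grid
# ---------------------------------------------------------------------------

@dataclass
class CorrelationCell:
    r: float
    raw_p: float
    corrected_p: float
    n: int
    method: str  # 'pearson' or 'spearman' (normality fallback)
    flagged: bool = False


@dataclass
class CorrelationTable:
    cells: dict[tuple[str, str], CorrelationCell]  # (behavior, neural) -> cell
    n_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "behavior_feature": b,
                "neural_feature": m,
                "r": c.r,
                "raw_p": c.raw_p,
                "corrected_p": c.corrected_p,
                "n": c.n,
                "method": c.method,
                "flagged": c.flagged,
            }
            for (b, m), c in self.cells.items()
        ]
        return pd.DataFrame(rows)


def _minmax_scale_0_100(v: pd.Series) -> pd.Series:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return pd.Series(np.zeros(len(v)), index=v.index)
    return 100.0 * (v - lo) / (hi - lo)


def behavior_neural_correlation(
    behavior: pd.DataFrame,
    neural: pd.DataFrame,
    behavior_cols: list[str] | None = None,
    neural_cols: list[str] | None = None,
    min_points: int = 3,
) -> CorrelationTable:
    """Correlate behavioral and interneuron response features per stimulus.

    ``behavior`` has one row per (bird, stimulus); ``neural`` one row per
    (unit, bird, stimulus).  Behavioral features are min-max normalized per
    bird and neural features per neuron, both scaled 0–100; neural features
    are then averaged across each bird's units per stimulus and joined on
    (bird, stimulus).  Pearson r per cell with Bonferroni correction over the
    grid; cells whose variables fail a Kolmogorov-Smirnov normality screen
    fall back to Spearman and are flagged.  Cells with fewer than
    ``min_points`` joined points are flagged and not computed.
    """
    bcols = behavior_cols or BEHAVIOR_COLS
    ncols = neural_cols or NEURAL_COLS
    b = behavior.dropna(subset=bcols).copy()
    for c in bcols:
        b[c] = b.groupby("bird_id")[c].transform(_minmax_scale_0_100)
    n = neural.dropna(subset=ncols).copy()
    for c in ncols:
        n[c] = n.groupby("unit_id")[c].transform(_minmax_scale_0_100)
    n_avg = n.groupby(["bird_id", "stimulus_id"])[ncols].mean().reset_index()
    joined = b.merge(n_avg, on=["bird_id", "stimulus_id"], suffixes=("_beh", "_neu"))

    n_comp = len(bcols) * len(ncols)
    cells: dict[tuple[str, str], CorrelationCell] = {}
    for bc in bcols:
        for nc in ncols:
            bc_col = bc + "_beh" if bc + "_beh" in joined else bc
            nc_col = nc + "_neu" if nc + "_neu" in joined else nc
            sub = joined[[bc_col, nc_col]].dropna()
            if len(sub) < min_points:
                cells[(bc, nc)] = CorrelationCell(np.nan, np.nan, np.nan, len(sub), "none", True)
                continue
            x = sub[bc_col].to_numpy()
            y = sub[nc_col].to_numpy()
            normal = _ks_normal(x) and _ks_normal(y)
            if normal:
                r, p = stats.pearsonr(x, y)
                method, flag = "pearson", False
            else:
                r, p = stats.spearmanr(x, y)
                method, flag = "spearman", True
            cells[(bc, nc)] = CorrelationCell(
                float(r), float(p), min(1.0, float(p) * n_comp), len(sub), method, flag
            )
    return CorrelationTable(cells=cells, n_comparisons=n_comp)


def _ks_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return False
    _, p = stats.kstest((x - np.mean(x)) / sd, "norm")
    return p > alpha


# ---------------------------------------------------------------------------
# normalized cross-correlation
# ---------------------------------------------------------------------------

def normalized_crosscorr(
    x: np.ndarray, y: np.ndarray, max_lag_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Length- and SD-normalized cross-correlation over ±``max_lag_bins``.

    ``c(ℓ) = Σ_t x(t+ℓ)·y(t) / (N·sd(x)·sd(y))`` with both series
    mean-centered and N the full signal length, bounding coefficients in
    [-1, 1].  Negative best lag ⇒ x leads y.  Returns ``(lags, c)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    # full cross-correlation: full[k] = sum_t xc[t + (k - (n-1))] * yc[t]
    full = np.correlate(xc, yc, mode="full")
    c = full[(n - 1) + lags] / (n * sx * sy)
    return lags, c


def best_lag(lags: np.ndarray, c: np.ndarray) -> tuple[int, float]:
    """Lag maximizing the coefficient (earliest on exact ties)."""
    i = int(np.argmax(c))
    return int(lags[i]), float(c[i])


# ---------------------------------------------------------------------------
# interneuron -> projection-neuron lag summary
# ---------------------------------------------------------------------------

@dataclass
class CrossCorrResult:
    per_interneuron: pd.DataFrame  # unit_id, mean_coefficient, mean_best_lag_ms
    spearman_rho: float
    spearman_p: float
    bin_ms: float


def interneuron_pn_lags(
    narrow_rates: dict[str, dict[str, np.ndarray]],
    broad_rates: dict[str, dict[str, np.ndarray]],
    max_lag_ms: float = 100.0,
    bin_ms: float = 1.0,
) -> CrossCorrResult:
    """Cross-correlate each interneuron against all simultaneously recorded
    projection neurons.

    ``narrow_rates``/``broad_rates`` map unit_id -> condition -> peri-stimulus
    rate series (equal length, ``bin_ms`` bins, typically −100 to 400 ms
    around playback onset).  Both conditions' mean-centered series are
    concatenated before correlating, so one coefficient/lag pair comes out
    per (interneuron, projection neuron) comparison.  Per interneuron the
    best-lag coefficients and lags are averaged over projection neurons; the
    population result is the Spearman correlation between mean coefficient
    and mean lag across interneurons.
    """
    if not broad_rates:
        raise ValueError("need at least one broad (projection) unit")
    max_lag_bins = int(round(max_lag_ms / bin_ms))

    def _concat(cond_rates: dict[str, np.ndarray], keys) -> np.ndarray:
        return np.concatenate([cond_rates[k] - np.mean(cond_rates[k]) for k in keys])

    rows = []
    for nid, ncond in narrow_rates.items():
        coefs, lags_ms = [], []
        for _bid, bcond in broad_rates.items():
            shared = sorted(set(ncond) & set(bcond))
            if not shared:
                continue
            xr = _concat(ncond, shared)
            yr = _concat(bcond, shared)
            if np.std(xr) == 0 or np.std(yr) == 0:
                continue
            lags, c = normalized_crosscorr(xr, yr, max_lag_bins)
            lag, coef = best_lag(lags, c)
            coefs.append(coef)
            lags_ms.append(lag * bin_ms)
        if coefs:
            rows.append(
                {
                    "unit_id": nid,
                    "mean_coefficient": float(np.mean(coefs)),
                    "mean_best_lag_ms": float(np.mean(lags_ms)),
                    "n_pairs": len(coefs),
                }
            )
    per = pd.DataFrame(rows)
    if len(per) >= 3:
        rho, p = stats.spearmanr(per["mean_coefficient"], per["mean_best_lag_ms"])
    else:
        rho, p = np.nan, np.nan
    return CrossCorrResult(
        per_interneuron=per,
        spearman_rho=float(rho),
        spearman_p=float(p),
        bin_ms=bin_ms,
    )
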