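"""Population-level condition comparison.

PCA state-space trajectories of the z-scored population response, a
shuffle-calibrated Euclidean-distance divergence between conditions, linear
SVM familiarity decoding with a label-permutation null (full window or
restricted sub-windows), and linear mixed-model contrasts of response
features with random intercepts for unit nested in bird.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .behavior import ClassifierResult, permutation_calibrated_classifier
from .config import FAMILIAR, UNFAMILIAR, ClassifierConfig

__all__ = [
    "DivergenceResult",
    "LMMResult",
    "TrajectorySet",
    "decode_familiarity_neural",
    "decode_from_features",
    "euclidean_divergence",
    "lmm_compare",
    "pca_trajectories",
]


# ---------------------------------------------------------------------------
# PCA trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySet:
    """Shared-space PC score time series per condition.

    The PCA is fit on the two conditions' (units × time) matrices
    concatenated along time, with units as features and time points as
    observations, so both trajectories live in one PC space.
    """

    loadings: np.ndarray  # (n_components, n_units)
    scores: dict[str, np.ndarray]  # condition -> (n_time, n_components)
    variance_explained: np.ndarray
    time_bins_ms: np.ndarray
    mean_: np.ndarray

    def smoothed_scores(self, sigma_bins: float = 3.0) -> dict[str, np.ndarray]:
        """Display smoothing (Gaussian kernel, width 3 bins by default)."""
        return {
            c: gaussian_filter1d(s, sigma=sigma_bins, axis=0)
            for c, s in self.scores.items()
        }


def pca_trajectories(
    condition_matrices: dict[str, np.ndarray],
    time_bins_ms: np.ndarray,
    n_components: int | None = None,
) -> TrajectorySet:
    """Fit PCA on the concatenated condition matrices and project each.

    ``condition_matrices`` maps condition -> (units × time) array of z-scored
    PSTHs; all conditions must share the unit set and time base.
    """
    mats = list(condition_matrices.values())
    n_units = mats[0].shape[0]
    if n_units < 2:
        raise ValueError("need at least 2 units")
    for m in mats:
        if m.shape != mats[0].shape:
            raise ValueError("conditions must share unit set and time base")
    X = np.concatenate([m.T for m in mats], axis=0)  # (time*cond, units)
    k = n_components or min(X.shape)
    if k > min(X.shape):
        raise ValueError("fewer units than requested components")
    pca = PCA(n_components=k)
    pca.fit(X)
    scores = {c: pca.transform(m.T) for c, m in condition_matrices.items()}
    return TrajectorySet(
        loadings=pca.components_,
        scores=scores,
        variance_explained=pca.explained_variance_ratio_,
        time_bins_ms=np.asarray(time_bins_ms),
        mean_=pca.mean_,
    )


# ---------------------------------------------------------------------------
# Euclidean-distance divergence
# ---------------------------------------------------------------------------

@dataclass
class DivergenceResult:
    time_bins_ms: np.ndarray
    distance: np.ndarray
    n_pcs: int
    null_mean: float
    null_sd: float
    threshold_low: float
    threshold_high: float
    significant: np.ndarray  # boolean per bin


def _auto_n_pcs(variance_explained: np.ndarray, threshold: float = 0.90) -> int:
    cum = np.cumsum(variance_explained)
    return int(np.searchsorted(cum, threshold) + 1)


def euclidean_divergence(
    trajectories: TrajectorySet,
    conditions: tuple[str, str] = (FAMILIAR, UNFAMILIAR),
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
    n_shuffle: int = 1000,
    n_pcs: int | None = None,
    seed: int = 0,
) -> DivergenceResult:
    """Between-condition Euclidean distance over time with a baseline null.

    Distance per bin is taken over the first ``n_pcs`` PCs (default: smallest
    number explaining ≥90% of the variance).  The null shuffles the pooled
    baseline-window score values of each PC (both conditions) ``n_shuffle``
    times, recomputing the between-condition distances from the shuffled
    values; bins whose distance falls outside the null mean ± 2 SD are
    flagged significant.
    """
    a, b = (trajectories.scores[c] for c in conditions)
    if n_pcs is None:
        n_pcs = _auto_n_pcs(trajectories.variance_explained)
    n_pcs = min(n_pcs, a.shape[1])
    d = np.linalg.norm(a[:, :n_pcs] - b[:, :n_pcs], axis=1)
    t = trajectories.time_bins_ms
    base = (t >= baseline_window_ms[0]) & (t < baseline_window_ms[1])
    if not np.any(base):
        raise ValueError("baseline window empty")
    rng = np.random.default_rng(seed)
    n_base = int(np.sum(base))
    null = np.empty((n_shuffle, n_base))
    pools = [
        np.concatenate([a[base, k], b[base, k]]) for k in range(n_pcs)
    ]  # per-PC pooled baseline values across both conditions
    for s in range(n_shuffle):
        sq = np.zeros(n_base)
        for k in range(n_pcs):
            aa = rng.choice(pools[k], size=n_base, replace=True)
            bb = rng.choice(pools[k], size=n_base, replace=True)
            sq += (aa - bb) ** 2
        null[s] = np.sqrt(sq)
    mu, sd = float(np.mean(null)), float(np.std(null))
    lo, hi = mu - 2 * sd, mu + 2 * sd
    return DivergenceResult(
        time_bins_ms=t,
        distance=d,
        n_pcs=n_pcs,
        null_mean=mu,
        null_sd=sd,
        threshold_low=lo,
        threshold_high=hi,
        significant=(d < lo) | (d > hi),
    )


# ---------------------------------------------------------------------------
# SVM decoding
# ---------------------------------------------------------------------------

def _minmax_per_neuron(fam: np.ndarray, unf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize each neuron's paired sample vectors jointly."""
    both = np.concatenate([fam, unf], axis=1)
    lo = both.min(axis=1, keepdims=True)
    hi = both.max(axis=1, keepdims=True)
    rng_ = np.where(hi - lo == 0, 1.0, hi - lo)
    return (fam - lo) / rng_, (unf - lo) / rng_


def decode_familiarity_neural(
    fam_matrix: np.ndarray,
    unf_matrix: np.ndarray,
    time_bins_ms: np.ndarray | None = None,
    window_ms: tuple[float, float] | None = None,
    cfg: ClassifierConfig | None = None,
) -> ClassifierResult:
    """Linear-SVM familiarity decoding from per-neuron condition responses.

    Each neuron contributes one familiar and one unfamiliar sample (its
    trial-averaged z vector over the analysis window); samples are min-max
    normalized per neuron; splits are stratified with a 0.1 test fraction by
    default.  ``window_ms`` restricts the time base (e.g. 0–100 ms vs
    100–400 ms sub-window decoding).
    """
    if fam_matrix.shape != unf_matrix.shape:
        raise ValueError("condition matrices must share shape")
    if fam_matrix.shape[0] < 2:
        raise ValueError("need at least 2 units")
    cfg = cfg or ClassifierConfig(test_frac=0.1)
    fam, unf = fam_matrix, unf_matrix
    if window_ms is not None:
        if time_bins_ms is None:
            raise ValueError("window_ms requires time_bins_ms")
        m = (time_bins_ms >= window_ms[0]) & (time_bins_ms <= window_ms[1])
        fam, unf = fam[:, m], unf[:, m]
    fam, unf = _minmax_per_neuron(fam, unf)
    X = np.concatenate([fam, unf], axis=0)
    y = np.array([FAMILIAR] * fam.shape[0] + [UNFAMILIAR] * unf.shape[0])
    return permutation_calibrated_classifier(X, y, "svm", cfg, subsample=False)


def decode_from_features(
    features: pd.DataFrame,
    feature_cols: list[str],
    cfg: ClassifierConfig | None = None,
) -> ClassifierResult:
    """SVM decoding from response features instead of time series.

    ``features`` has one row per (unit, condition); each feature is min-max
    normalized per unit across its condition rows.
    """
    cfg = cfg or ClassifierConfig(test_frac=0.1)
    wide = features.pivot_table(
        index="unit_id", columns="condition", values=feature_cols
    ).dropna()  # units must contribute both conditions
    fam = np.column_stack([wide[(c, FAMILIAR)] for c in feature_cols])
    unf = np.column_stack([wide[(c, UNFAMILIAR)] for c in feature_cols])
    fam, unf = _minmax_per_neuron(fam, unf)
    X = np.concatenate([fam, unf], axis=0)
    y = np.array([FAMILIAR] * fam.shape[0] + [UNFAMILIAR] * unf.shape[0])
    return permutation_calibrated_classifier(X, y, "svm", cfg, subsample=False)


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    feature_name: str
    estimate: float  # fixed effect of familiarity (familiar − unfamiliar)
    se: float
    p: float
    random_effects: str
    singular: bool


def lmm_compare(
    features: pd.DataFrame,
    feature_cols: list[str],
    group_cols: tuple[str, str] = ("bird_id", "unit_id"),
) -> list[LMMResult]:
    """Mixed-model familiarity contrast per feature.

    Fits ``value ~ familiarity`` with a random intercept per bird and a
    variance component for unit nested in bird; reports the Wald p of the
    familiarity fixed effect.  Singular/non-converged fits are flagged, not
    dropped.
    """
    bird_col, unit_col = group_cols
    out = []
    for feat in feature_cols:
        df = features[[bird_col, unit_col, "condition", feat]].dropna().copy()
        df = df.rename(columns={feat: "value", bird_col: "bird", unit_col: "unit"})
        df["fam"] = (df["condition"] == FAMILIAR).astype(float)
        singular = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(
                    "value ~ fam",
                    df,
                    groups=df["bird"],
                    re_formula="1",
                    vc_formula={"unit": "0 + C(unit)"},
                )
                fit = model.fit(reml=True, method="lbfgs")
                if not fit.converged:
                    singular = True
                est = float(fit.params["fam"])
                se = float(fit.bse["fam"])
                p = float(fit.pvalues["fam"])
            except (np.linalg.LinAlgError, ValueError):
                singular = True
                ols = sm.OLS(df["value"], sm.add_constant(df["fam"])).fit()
                est, se, p = (
                    float(ols.params["fam"]),
                    float(ols.bse["fam"]),
                    float(ols.pvalues["fam"]),
                )
        out.append(
            LMMResult(
                feature_name=feat,
                estimate=est,
                se=se,
                p=p,
                random_effects="intercept~bird + vc(unit in bird)",
                singular=singular,
            )
        )
    return out
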