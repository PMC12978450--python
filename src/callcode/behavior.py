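"""Vocal-response quantification and behavioral familiarity classification.

A "response" is the first contact-call onset after a playback onset and
before the next playback onset; later calls in the same interval are ignored
for latency.  Per-(bird, stimulus) features — peak response probability,
median response latency and latency variability — feed a Wilcoxon
signed-rank familiar/unfamiliar comparison and a permutation-calibrated
random-forest familiarity classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .config import FAMILIAR, UNFAMILIAR, ClassifierConfig

__all__ = [
    "ClassifierResult",
    "behavioral_features",
    "classify_familiarity_behavior",
    "first_response_latencies",
    "minmax_normalize_per_group",
    "paired_condition_test",
    "response_time_distribution",
]

BEHAVIOR_FEATURES = ["peak_response_prob", "response_latency_ms", "latency_variability_ms"]


# ---------------------------------------------------------------------------
# response timing
# ---------------------------------------------------------------------------

def _check_trials(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials.sort_values("onset_s").reset_index(drop=True)
    if np.any(t["offset_s"].to_numpy() <= t["onset_s"].to_numpy()):
        raise ValueError("trial offset must exceed onset")
    if np.any(t["onset_s"].to_numpy()[1:] < t["offset_s"].to_numpy()[:-1]):
        raise ValueError("overlapping trials")
    return t


def first_response_latencies(
    trials: pd.DataFrame, responses: pd.DataFrame
) -> pd.DataFrame:
    """First-response latency per trial (ms from playback onset; NaN if unanswered).

    The response window of a trial runs from its playback onset to the next
    trial's onset (unbounded for the final trial).  Responses whose onset
    precedes the playback onset are never attributed to that trial.
    """
    t = _check_trials(trials)
    onsets = t["onset_s"].to_numpy()
    next_onset = np.append(onsets[1:], np.inf)
    r_on = np.sort(responses["onset_s"].to_numpy()) if len(responses) else np.array([])
    lat = np.full(len(t), np.nan)
    for i in range(len(t)):
        j = np.searchsorted(r_on, onsets[i], side="left")
        if j < r_on.size and r_on[j] < next_onset[i]:
            lat[i] = (r_on[j] - onsets[i]) * 1000.0
    out = t[["trial_id", "stimulus_id", "familiarity", "onset_s"]].copy()
    out["latency_ms"] = lat
    return out


def response_time_distribution(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    bin_ms: float = 50.0,
    span_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Response-probability histogram over the inter-playback interval.

    Bin *b* holds the fraction of trials whose first response fell in *b*
    (relative to playback onset); the histogram therefore sums to the overall
    answered fraction.  Returns ``(bin_left_edges_ms, probability)``.
    """
    t = _check_trials(trials)
    if span_ms is None:
        diffs = np.diff(t["onset_s"].to_numpy()) * 1000.0
        span_ms = float(np.min(diffs)) if diffs.size else 1000.0
    n_bins = span_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_ms={bin_ms} does not divide the {span_ms} ms interval")
    edges = np.arange(0.0, span_ms + bin_ms / 2, bin_ms)
    lat = first_response_latencies(t, responses)["latency_ms"].to_numpy()
    counts = np.histogram(lat[~np.isnan(lat)], bins=edges)[0]
    return edges[:-1], counts / len(t)


# ---------------------------------------------------------------------------
# per-(bird, stimulus) features
# ---------------------------------------------------------------------------

def behavioral_features(
    trials: pd.DataFrame,
    responses: pd.DataFrame,
    bird_id: str,
    bin_ms: float = 50.0,
) -> pd.DataFrame:
    """Feature row per stimulus: peak response probability (max histogram
    bin), median first-response latency, and latency standard deviation.

    Latency is NaN-flagged with zero responses; variability additionally
    requires at least two responses.
    """
    lat = first_response_latencies(trials, responses)
    rows = []
    for stim, grp in lat.groupby("stimulus_id", sort=True):
        sub_trials = trials[trials["stimulus_id"] == stim]
        sub_resp_lat = grp["latency_ms"].dropna().to_numpy()
        _, hist = response_time_distribution(
            sub_trials.reset_index(drop=True),
            responses,
            bin_ms=bin_ms,
            span_ms=_common_span_ms(trials),
        )
        n = sub_resp_lat.size
        rows.append(
            {
                "bird_id": bird_id,
                "stimulus_id": stim,
                "familiarity": grp["familiarity"].iloc[0],
                "peak_response_prob": float(np.max(hist)) if hist.size else 0.0,
                "response_latency_ms": float(np.median(sub_resp_lat)) if n else np.nan,
                "latency_variability_ms": float(np.std(sub_resp_lat, ddof=1)) if n >= 2 else np.nan,
                "n_responses": int(n),
            }
        )
    return pd.DataFrame(rows)


def _common_span_ms(trials: pd.DataFrame) -> float:
    diffs = np.diff(np.sort(trials["onset_s"].to_numpy())) * 1000.0
    return float(np.min(diffs)) if diffs.size else 1000.0




# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

def paired_condition_test(
    features: pd.DataFrame, feature_name: str
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on familiar-vs-unfamiliar pairs.

    Each familiar (bird, stimulus) row is paired with the mean of that bird's
    unfamiliar rows.  Returns ``(statistic, p, degenerate)``; all-zero
    differences make the test undefined and return p = 1 with the flag set.
    """
    fam = features[features["familiarity"] == FAMILIAR]
    unf_mean = (
        features[features["familiarity"] == UNFAMILIAR]
        .groupby("bird_id")[feature_name]
        .mean()
    )
    pairs = [
        (row[feature_name], unf_mean[row["bird_id"]])
        for _, row in fam.iterrows()
        if row["bird_id"] in unf_mean.index
        and np.isfinite(row[feature_name])
        and np.isfinite(unf_mean[row["bird_id"]])
    ]
    if len(pairs) < 2:
        raise ValueError("fewer than 2 usable familiar/unfamiliar pairs")
    x = np.array([a for a, _ in pairs])
    y = np.array([b for _, b in pairs])
    if np.allclose(x, y):
        return 0.0, 1.0, True
    stat, p = stats.wilcoxon(x, y, alternative="two-sided", method="auto")
    return float(stat), float(p), False


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def minmax_normalize_per_group(
    df: pd.DataFrame, feature_cols: list[str], group_col: str
) -> pd.DataFrame:
    """Min-max normalize each feature within each group (e.g. per bird).

    Constant features within a group map to 0.  Applied before any
    subsampling or splitting, so the classifier sees only within-group
    relative values.
    """
    out = df.copy()
    for _, idx in df.groupby(group_col).groups.items():
        for c in feature_cols:
            v = df.loc[idx, c].astype(float)
            lo, hi = v.min(), v.max()
            out.loc[idx, c] = 0.0 if hi == lo else (v - lo) / (hi - lo)
    return out


@dataclass
class ClassifierResult:
    """Accuracy distribution of a permutation-calibrated classifier.

    The null holds one accuracy per label permutation (the classifier is
    rerun several times per permutation and averaged).  ``p_value`` is the
    proportion of null accuracies strictly exceeding the observed mean;
    ``chance_level`` is the null mean and ``null_ci95`` the value below which
    95% of null accuracies fall.
    """

    accuracies: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray  # mean over iterations, rows = true class
    null_accuracies: np.ndarray
    chance_level: float
    null_ci95: float
    p_value: float
    classes: tuple[str, str] = (FAMILIAR, UNFAMILIAR)

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": float(np.std(self.accuracies)),
            "chance_level": self.chance_level,
            "null_ci95": self.null_ci95,
            "p_value": self.p_value,
            "n_iter": int(self.accuracies.size),
            "n_null": int(self.null_accuracies.size),
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
        }


def _make_clf(kind: str, cfg: ClassifierConfig, seed: int):
    if kind == "rf":
        return RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed)
    if kind == "svm":
        return SVC(kernel="linear", C=cfg.svm_c, random_state=seed)
    raise ValueError(kind)


def _balanced_accuracy_runs(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    cfg: ClassifierConfig,
    rng: np.random.Generator,
    n_runs: int,
    subsample: bool,
    collect_confusion: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeated subsample/stratified-split/fit/score runs.

    With ``subsample`` the majority class is randomly downsampled to the
    minority count each run.  Degenerate single-class folds are resampled.
    """
    classes = np.unique(y)
    accs = np.empty(n_runs)
    conf = np.zeros((2, 2))
    for r in range(n_runs):
        if subsample:
            idx = []
            n_min = min(np.sum(y == c) for c in classes)
            for c in classes:
                pool = np.flatnonzero(y == c)
                idx.append(rng.choice(pool, size=n_min, replace=False))
            idx = np.concatenate(idx)
        else:
            idx = np.arange(y.size)
        Xs, ys = X[idx], y[idx]
        for _attempt in range(20):
            split_seed = int(rng.integers(2**31 - 1))
            Xtr, Xte, ytr, yte = train_test_split(
                Xs, ys, test_size=cfg.test_frac, stratify=ys, random_state=split_seed
            )
            if np.unique(ytr).size == 2 and np.unique(yte).size >= 1:
                break
        clf = _make_clf(kind, cfg, split_seed)
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        accs[r] = float(np.mean(pred == yte))
        if collect_confusion:
            for ci, ctrue in enumerate(classes):
                for cj, cpred in enumerate(classes):
                    conf[ci, cj] += np.sum((yte == ctrue) & (pred == cpred))
    if collect_confusion and conf.sum():
        conf = conf / conf.sum(axis=1, keepdims=True).clip(min=1)
    return accs, conf


def permutation_calibrated_classifier(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    cfg: ClassifierConfig,
    subsample: bool = False,
) -> ClassifierResult:
    """Observed accuracy distribution plus a label-permutation null.

    The observed mean is the average test accuracy over ``n_iter``
    random stratified splits; the null permutes labels ``n_perm`` times and
    reruns the classifier ``runs_per_perm`` times per permutation.
    """
    rng = np.random.default_rng(cfg.seed)
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if min(np.bincount(pd.factorize(y)[0])) < 2:
        raise ValueError("need at least 2 samples per class")
    accs, conf = _balanced_accuracy_runs(
        X, y, kind, cfg, rng, cfg.n_iter, subsample, collect_confusion=True
    )
    # one null accuracy per permutation: the mean over runs_per_perm reruns
    null = np.empty(cfg.n_perm)
    for pidx in range(cfg.n_perm):
        yp = rng.permutation(y)
        a, _ = _balanced_accuracy_runs(
            X, yp, kind, cfg, rng, cfg.runs_per_perm, subsample
        )
        null[pidx] = float(np.mean(a))
    mean_acc = float(np.mean(accs))
    return ClassifierResult(
        accuracies=accs,
        mean_accuracy=mean_acc,
        confusion=conf,
        null_accuracies=null,
        chance_level=float(np.mean(null)),
        null_ci95=float(np.percentile(null, 95)),
        p_value=float(np.mean(null > mean_acc)),
    )


def classify_familiarity_behavior(
    features: pd.DataFrame,
    cfg: ClassifierConfig | None = None,
) -> ClassifierResult:
    """Random-forest familiarity classification from behavioral features.

    Features are min-max normalized per bird before anything else; unfamiliar
    rows are randomly subsampled to the familiar count on every iteration;
    splits are stratified 50/50 by default.  Rows with undefined latency
    features are dropped.
    """
    cfg = cfg or ClassifierConfig()
    df = features.dropna(subset=BEHAVIOR_FEATURES).reset_index(drop=True)
    df = minmax_normalize_per_group(df, BEHAVIOR_FEATURES, "bird_id")
    X = df[BEHAVIOR_FEATURES].to_numpy(dtype=float)
    y = df["familiarity"].to_numpy()
    return permutation_calibrated_classifier(X, y, "rf", cfg, subsample=True)
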