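"""Playback preprocessing and acoustic-similarity clustering.

Clips are peak-normalized and zero-phase band-pass filtered (300 Hz –
14 kHz by default), then clustered by PCA on their waveform samples followed
by silhouette-selected k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .synthgen import AudioClip

__all__ = ["ClusterResult", "cluster_playbacks", "preprocess_playback"]

DEFAULT_BAND_HZ = (300.0, 14000.0)


def preprocess_playback(
    clip: AudioClip, band_hz: tuple[float, float] = DEFAULT_BAND_HZ, order: int = 6
) -> AudioClip:
    """Peak-normalize to [-1, 1] and apply a zero-phase Butterworth band-pass.

    Silent clips skip normalization (flagged by leaving the samples at zero).
    The sample rate must exceed twice the upper band edge.
    """
    x = np.asarray(clip.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    if clip.sample_rate_hz <= 2 * band_hz[1]:
        raise ValueError("sample rate must exceed twice the upper band edge")
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    sos = butter(order, band_hz, btype="bandpass", fs=clip.sample_rate_hz, output="sos")
    y = sosfiltfilt(sos, x) if x.size > 30 else x
    return AudioClip(
        samples=y,
        sample_rate_hz=clip.sample_rate_hz,
        stimulus_id=clip.stimulus_id,
        familiarity_role=clip.familiarity_role,
        cluster_truth=clip.cluster_truth,
    )


@dataclass
class ClusterResult:
    coordinates: np.ndarray  # clips × retained PCs
    variance_explained: np.ndarray
    silhouette: dict[int, float]
    chosen_k: int
    labels: np.ndarray
    degenerate: bool = False


def _align_and_pad(clips: list[AudioClip], onset_frac: float = 0.05) -> np.ndarray:
    """Align clips at their first threshold crossing and zero-pad to a common
    length."""
    aligned = []
    for c in clips:
        x = np.asarray(c.samples, dtype=float)
        peak = np.max(np.abs(x))
        if peak == 0:
            aligned.append(x)
            continue
        idx = np.flatnonzero(np.abs(x) >= onset_frac * peak)
        aligned.append(x[idx[0]:])
    n = max(a.size for a in aligned)
    return np.vstack([np.pad(a, (0, n - a.size)) for a in aligned])


def cluster_playbacks(
    clips: list[AudioClip],
    k_range: range = range(2, 6),
    variance_threshold: float = 0.90,
    decimate: int = 1,
    seed: int = 0,
) -> ClusterResult:
    """PCA on waveform samples, silhouette-selected k, then k-means.

    PCs are retained up to ``variance_threshold`` cumulative variance; the
    silhouette score is evaluated on the PC coordinates for every candidate
    k and the argmax wins.  All-identical clips are flagged degenerate.
    """
    if len(clips) < max(k_range) + 1:
        raise ValueError("need more clips than the largest candidate k")
    X = _align_and_pad(clips)[:, ::decimate]
    if np.allclose(X, X[0]):
        return ClusterResult(
            coordinates=np.zeros((len(clips), 1)),
            variance_explained=np.array([np.nan]),
            silhouette={},
            chosen_k=1,
            labels=np.zeros(len(clips), dtype=int),
            degenerate=True,
        )
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    coords_full = pca.fit_transform(X)
    n_pcs = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), variance_threshold) + 1)
    coords = coords_full[:, :n_pcs]
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(coords)
        labels_by_k[k] = lab
        sil[k] = float(silhouette_score(coords, lab)) if np.unique(lab).size > 1 else -1.0
    chosen = max(sil, key=sil.get)
    return ClusterResult(
        coordinates=coords,
        variance_explained=pca.explained_variance_ratio_[:n_pcs],
        silhouette=sil,
        chosen_k=int(chosen),
        labels=labels_by_k[chosen],
    )
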