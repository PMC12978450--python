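"""End-to-end orchestration: synth → behavior → units → population → coupling
→ acoustics, with seed fan-out, a serializable run configuration and a
machine-readable results bundle.

The global seed fans out to per-stage seeds through ``numpy``'s seeding
machinery so stages are reproducible independently of one another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import acoustics, behavior, coupling, io, population, units
from .config import (
    BROAD,
    FAMILIAR,
    NARROW,
    UNFAMILIAR,
    ClassifierConfig,
    QCThresholds,
    SynthConfig,
)
from .synthgen import RecordingSession, gen_call_audio, gen_paired_dataset

__all__ = ["RunConfig", "run_pipeline", "session_psths", "session_features"]


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "results/run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    clf_behavior: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(n_iter=200, test_frac=0.5, n_perm=200, runs_per_perm=5)
    )
    clf_neural: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(n_iter=200, test_frac=0.1, n_perm=200, runs_per_perm=5)
    )
    bin_ms: float = 10.0
    histogram_bin_ms: float = 50.0
    n_pcs: int | None = None  # None = smallest set explaining >=90% variance
    n_shuffle: int = 1000
    max_lag_ms: float = 100.0
    n_audio_clusters: int = 2
    write_audio: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        d["synth"] = SynthConfig.from_dict(d.get("synth", {}))
        d["qc"] = QCThresholds(**d.get("qc", {}))
        d["clf_behavior"] = ClassifierConfig(**d.get("clf_behavior", {}))
        d["clf_neural"] = ClassifierConfig(**d.get("clf_neural", {}))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: Path | str) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, sum(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# neural helpers shared by pipeline, tests and the acceptance script
# ---------------------------------------------------------------------------

def session_psths(
    session: RecordingSession,
    bin_ms: float = 10.0,
    smoothing: str = "gaussian",
    window_ms: tuple[float, float] = (-400.0, 400.0),
    baseline_window_ms: tuple[float, float] | None = None,
    by: str = "familiarity",
) -> dict[str, dict[str, units.ZScoredPSTH]]:
    """Z-scored PSTH per unit per condition (or per stimulus, ``by="stimulus_id"``)."""
    if baseline_window_ms is None:
        baseline_window_ms = (window_ms[0], 0.0)
    out: dict[str, dict[str, units.ZScoredPSTH]] = {}
    groups = session.trials.groupby(by)["onset_s"]
    all_onsets = session.trials["onset_s"].to_numpy()
    # one z scale across groups even when trial counts differ per condition
    reference_n = int(min(len(g) for _, g in groups))
    for u in session.units:
        per = {}
        for key, onsets in groups:
            z = units.psth_zscore(
                u.spike_times_s,
                onsets.to_numpy(),
                unit_id=u.unit_id,
                condition=str(key),
                bin_ms=bin_ms,
                window_ms=window_ms,
                baseline_window_ms=baseline_window_ms,
                smoothing=smoothing,
                baseline_onsets_s=all_onsets,
                reference_n=reference_n,
            )
            if not z.flagged:
                per[str(key)] = z
        if per:
            out[u.unit_id] = per
    return out


def session_features(
    psths: dict[str, dict[str, units.ZScoredPSTH]]
) -> pd.DataFrame:
    """Response features per (unit, condition) row."""
    rows = []
    for uid, per in psths.items():
        for cond, z in per.items():
            f = units.response_features(z)
            rows.append(
                {
                    "unit_id": uid,
                    "condition": cond,
                    "mean_z": f.mean_z,
                    "max_z": f.max_z,
                    "time_of_max_ms": f.time_of_max_ms,
                    "response_duration_ms": f.response_duration_ms,
                    "responsive": f.responsive,
                }
            )
    return pd.DataFrame(rows)


def _condition_matrices(
    psths: dict[str, dict[str, units.ZScoredPSTH]],
    responsive_ids: list[str],
    window_ms: tuple[float, float] = (0.0, 400.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(familiar, unfamiliar) unit × time z matrices over the analysis window."""
    ids = [u for u in responsive_ids if FAMILIAR in psths[u] and UNFAMILIAR in psths[u]]
    any_z = psths[ids[0]][FAMILIAR]
    m = (any_z.time_bins_ms >= window_ms[0]) & (any_z.time_bins_ms <= window_ms[1])
    fam = np.vstack([psths[u][FAMILIAR].z[m] for u in ids])
    unf = np.vstack([psths[u][UNFAMILIAR].z[m] for u in ids])
    return fam, unf, any_z.time_bins_ms[m]


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage on freshly generated synthetic data.

    Writes stage tables plus ``results.json`` and a checksum manifest under
    ``config.out_dir`` and returns the results dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict[str, Any] = {"config": config.to_dict()}
    synth_cfg = dataclasses.replace(config.synth, seed=_stage_seed(config.seed, "synth"))

    try:
        # --- synth ---------------------------------------------------
        behavior_sessions, recording_sessions = gen_paired_dataset(synth_cfg)
        for s in behavior_sessions:
            written += io.write_behavior_session(s, out / "behavior")
        for r in recording_sessions:
            written += io.write_recording_session(r, out / "ephys")
        clips = gen_call_audio(synth_cfg, n_clusters=config.n_audio_clusters)
        if config.write_audio:
            for c in clips:
                written.append(io.write_wav(c, out / "audio" / f"{c.stimulus_id}.wav"))

        # --- behavior ------------------------------------------------
        feats = pd.concat(
            [
                behavior.behavioral_features(
                    s.trials, s.responses, s.bird_id, bin_ms=config.histogram_bin_ms
                )
                for s in behavior_sessions
            ],
            ignore_index=True,
        )
        written.append(io.write_tsv(feats, out / "behavior_features.tsv"))
        tests = {}
        for name in behavior.BEHAVIOR_FEATURES:
            try:
                stat, p, degenerate = behavior.paired_condition_test(feats, name)
                tests[name] = {"statistic": stat, "p": p, "degenerate": degenerate}
            except ValueError as exc:
                tests[name] = {"error": str(exc)}
        clf_b = dataclasses.replace(
            config.clf_behavior, seed=_stage_seed(config.seed, "clf_behavior")
        )
        rf = behavior.classify_familiarity_behavior(feats, clf_b)
        results["behavior"] = {"paired_tests": tests, "classifier": rf.to_dict()}

        # --- units ---------------------------------------------------
        all_psths: dict[str, dict[str, units.ZScoredPSTH]] = {}
        unit_class: dict[str, str] = {}
        unit_bird: dict[str, str] = {}
        qc_rows = []
        for r in recording_sessions:
            utab = pd.DataFrame(
                [{"unit_id": u.unit_id, **u.qc} for u in r.units]
            )
            retained, report = units.qc_filter(utab, config.qc)
            qc_rows.append(report)
            keep = set(retained["unit_id"])
            kept_units = [u for u in r.units if u.unit_id in keep]
            for u in kept_units:
                wf = units.classify_waveform(u.mean_waveform, u.waveform_sample_rate_khz)
                if wf.flagged:
                    continue
                unit_class[u.unit_id] = wf.putative_class
                unit_bird[u.unit_id] = r.bird_id
            psths = session_psths(
                RecordingSession(r.session_id, r.bird_id, r.trials, kept_units, r.ground_truth),
                bin_ms=config.bin_ms,
            )
            all_psths.update(psths)
        qc_report = pd.concat(qc_rows, ignore_index=True)
        written.append(io.write_tsv(qc_report, out / "qc_report.tsv"))
        feat_tab = session_features(all_psths)
        feat_tab["putative_class"] = feat_tab["unit_id"].map(unit_class)
        feat_tab["bird_id"] = feat_tab["unit_id"].map(unit_bird)
        written.append(io.write_tsv(feat_tab, out / "unit_features.tsv"))
        results["units"] = {
            "n_retained": int(qc_report["passed"].sum()),
            "n_total": int(len(qc_report)),
            "n_narrow": int(sum(1 for c in unit_class.values() if c == NARROW)),
            "n_broad": int(sum(1 for c in unit_class.values() if c == BROAD)),
        }

        # --- population ----------------------------------------------
        resp = feat_tab[feat_tab["responsive"]]
        results["population"] = {}
        clf_n = dataclasses.replace(
            config.clf_neural, seed=_stage_seed(config.seed, "clf_neural")
        )
        for cls in (NARROW, BROAD):
            ids = sorted(
                set(resp.loc[resp["putative_class"] == cls, "unit_id"])
            )
            ids = [
                u for u in ids
                if FAMILIAR in all_psths.get(u, {}) and UNFAMILIAR in all_psths.get(u, {})
            ]
            if len(ids) < 3:
                results["population"][cls] = {"skipped": f"only {len(ids)} responsive units"}
                continue
            fam, unf, tb = _condition_matrices(all_psths, ids)
            traj = population.pca_trajectories({FAMILIAR: fam, UNFAMILIAR: unf}, tb)
            # the divergence null needs pre-onset bins in the trajectory
            fam_full, unf_full, tb_full = _condition_matrices(
                all_psths, ids, window_ms=(-200.0, 400.0)
            )
            traj_full = population.pca_trajectories(
                {FAMILIAR: fam_full, UNFAMILIAR: unf_full}, tb_full
            )
            div = population.euclidean_divergence(
                traj_full,
                baseline_window_ms=(-100.0, 0.0),
                n_shuffle=config.n_shuffle,
                n_pcs=config.n_pcs,
                seed=_stage_seed(config.seed, f"divergence_{cls}"),
            )
            dec = population.decode_familiarity_neural(fam, unf, tb, cfg=clf_n)
            lmm = population.lmm_compare(
                resp[resp["putative_class"] == cls],
                ["mean_z", "max_z", "time_of_max_ms", "response_duration_ms"],
            )
            decf = population.decode_from_features(
                resp[resp["putative_class"] == cls],
                ["mean_z", "max_z", "response_duration_ms"],
                cfg=clf_n,
            )
            written.append(
                io.write_tsv(
                    pd.DataFrame(
                        {
                            "time_ms": div.time_bins_ms,
                            "distance": div.distance,
                            "significant": div.significant,
                        }
                    ),
                    out / f"divergence_{cls}.tsv",
                )
            )
            results["population"][cls] = {
                "variance_explained_2pc": float(np.sum(traj.variance_explained[:2])),
                "divergence_significant_frac": float(np.mean(div.significant)),
                "decoding": dec.to_dict(),
                "decoding_features": decf.to_dict(),
                "lmm": [dataclasses.asdict(r) for r in lmm],
            }

        # --- coupling ------------------------------------------------
        per_stim_feats = []
        lag_results = []
        for r in recording_sessions:
            psths_stim = session_psths(r, bin_ms=config.bin_ms, by="stimulus_id")
            f = session_features(psths_stim)
            f = f.rename(columns={"condition": "stimulus_id"})
            f["bird_id"] = r.bird_id
            f["putative_class"] = f["unit_id"].map(unit_class)
            per_stim_feats.append(f[f["putative_class"] == NARROW])
            # cross-correlations run on raw 1 ms binned rates (unsmoothed:
            # symmetric smoothing kernels shift the peak of an asymmetric
            # cross-correlation function)
            fine = session_psths(
                r, bin_ms=1.0, smoothing="none", window_ms=(-100.0, 400.0)
            )
            narrow_rates = {
                u.unit_id: {c: z.rate_hz for c, z in fine[u.unit_id].items()}
                for u in r.units
                if unit_class.get(u.unit_id) == NARROW and u.unit_id in fine
            }
            broad_rates = {
                u.unit_id: {c: z.rate_hz for c, z in fine[u.unit_id].items()}
                for u in r.units
                if unit_class.get(u.unit_id) == BROAD and u.unit_id in fine
            }
            if narrow_rates and broad_rates:
                lag_results.append(
                    coupling.interneuron_pn_lags(
                        narrow_rates, broad_rates, max_lag_ms=config.max_lag_ms
                    )
                )
        neural_stim = pd.concat(per_stim_feats, ignore_index=True)
        corr = coupling.behavior_neural_correlation(feats, neural_stim)
        written.append(io.write_tsv(corr.to_frame(), out / "behavior_neural_correlation.tsv"))
        per_int = pd.concat([l.per_interneuron for l in lag_results], ignore_index=True)
        written.append(io.write_tsv(per_int, out / "interneuron_lags.tsv"))
        from scipy import stats as sstats

        if len(per_int) >= 3:
            rho, rho_p = sstats.spearmanr(
                per_int["mean_coefficient"], per_int["mean_best_lag_ms"]
            )
        else:
            rho, rho_p = float("nan"), float("nan")
        results["coupling"] = {
            "spearman_rho": float(rho),
            "spearman_p": float(rho_p),
            "mean_best_lag_ms": float(per_int["mean_best_lag_ms"].mean()),
            "frac_negative_lag": float((per_int["mean_best_lag_ms"] < 0).mean()),
        }

        # --- acoustics -----------------------------------------------
        pre = [acoustics.preprocess_playback(c) for c in clips]
        cres = acoustics.cluster_playbacks(
            pre, seed=_stage_seed(config.seed, "acoustics")
        )
        results["acoustics"] = {
            "chosen_k": cres.chosen_k,
            "silhouette": {str(k): v for k, v in cres.silhouette.items()},
            "variance_explained": cres.variance_explained.tolist(),
            "labels": cres.labels.tolist(),
            "truth": [c.cluster_truth for c in clips],
        }
    except Exception as exc:  # partial-output manifest on stage failure
        _write_manifest(out, config, written, failed=repr(exc))
        raise

    res_path = out / "results.json"
    res_path.write_text(json.dumps(results, indent=2, default=float))
    written.append(res_path)
    _write_manifest(out, config, written)
    return results


def _write_manifest(
    out: Path, config: RunConfig, written: list[Path], failed: str | None = None
) -> None:
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "failed": failed,
        "files": {str(p.relative_to(out)): io.checksum(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
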