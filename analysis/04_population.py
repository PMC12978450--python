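"""Population-level familiarity analysis per waveform class: PCA
trajectories, Euclidean-distance divergence, SVM decoding (full and split
windows), feature-based decoding and mixed-model contrasts.

Writes results/population/.
"""

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_config

from callcode import io, population, units
from callcode.config import BROAD, FAMILIAR, NARROW, UNFAMILIAR
from callcode.pipeline import _condition_matrices, session_features, session_psths
from callcode.synthgen import gen_paired_dataset


def main() -> None:
    cfg = analysis_config()
    out = RESULTS / "population"
    out.mkdir(parents=True, exist_ok=True)
    _, recordings = gen_paired_dataset(cfg.synth)

    all_psths, classes, birds = {}, {}, {}
    for rec in recordings:
        for u in rec.units:
            wf = units.classify_waveform(u.mean_waveform, u.waveform_sample_rate_khz)
            if not wf.flagged:
                classes[u.unit_id] = wf.putative_class
                birds[u.unit_id] = rec.bird_id
        all_psths.update(session_psths(rec, bin_ms=cfg.bin_ms))
    feats = session_features(all_psths)
    feats["putative_class"] = feats["unit_id"].map(classes)
    feats["bird_id"] = feats["unit_id"].map(birds)
    resp = feats[feats["responsive"]]

    results = {}
    for cls in (NARROW, BROAD):
        ids = sorted(
            u for u in resp.loc[resp["putative_class"] == cls, "unit_id"].unique()
            if FAMILIAR in all_psths.get(u, {}) and UNFAMILIAR in all_psths.get(u, {})
        )
        print(f"\n== {cls}-waveform units (n = {len(ids)} responsive) ==")
        fam, unf, tb = _condition_matrices(all_psths, ids)
        fam_f, unf_f, tb_f = _condition_matrices(all_psths, ids, window_ms=(-200, 400))
        traj = population.pca_trajectories({FAMILIAR: fam_f, UNFAMILIAR: unf_f}, tb_f)
        div = population.euclidean_divergence(traj, n_shuffle=cfg.n_shuffle,
                                              seed=cfg.seed)
        print(f"variance explained by first 2 PCs: "
              f"{100 * traj.variance_explained[:2].sum():.1f}%")
        post = div.time_bins_ms >= 0
        print(f"divergence: {div.significant[post].mean():.1%} of post-onset bins "
              f"outside the baseline-shuffle band ({div.n_pcs} PCs)")

        dec = population.decode_familiarity_neural(fam, unf, tb, cfg=cfg.clf_neural)
        print(f"decoding (0-400 ms): {100 * dec.mean_accuracy:.1f}% "
              f"(chance {100 * dec.chance_level:.1f}%, p = {dec.p_value:.3f})")
        windows = {}
        for win in ((0.0, 100.0), (100.0, 400.0)):
            w = population.decode_familiarity_neural(
                fam, unf, tb, window_ms=win, cfg=cfg.clf_neural)
            windows[f"{int(win[0])}-{int(win[1])}ms"] = w.to_dict()
            print(f"decoding ({int(win[0])}-{int(win[1])} ms): "
                  f"{100 * w.mean_accuracy:.1f}%")
        decf = population.decode_from_features(
            resp[resp["putative_class"] == cls],
            ["mean_z", "max_z", "response_duration_ms"], cfg=cfg.clf_neural)
        print(f"decoding from response features: {100 * decf.mean_accuracy:.1f}% "
              f"(p = {decf.p_value:.3f})")
        lmm = population.lmm_compare(
            resp[resp["putative_class"] == cls],
            ["mean_z", "max_z", "time_of_max_ms", "response_duration_ms"])
        for r in lmm:
            print(f"LMM {r.feature_name}: estimate {r.estimate:+.3f} "
                  f"(p = {r.p:.4f}{', singular' if r.singular else ''})")
        io.write_tsv(
            pd.DataFrame({"time_ms": div.time_bins_ms, "distance": div.distance,
                          "significant": div.significant}),
            out / f"divergence_{cls}.tsv")
        results[cls] = {
            "n_responsive": len(ids),
            "variance_explained_2pc": float(np.sum(traj.variance_explained[:2])),
            "decoding": dec.to_dict(),
            "decoding_windows": windows,
            "decoding_features": decf.to_dict(),
            "lmm": [dataclasses.asdict(r) for r in lmm],
        }
    (out / "summary.json").write_text(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
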