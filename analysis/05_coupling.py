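"""Relate behavior to interneuron activity and measure narrow→broad timing.

Correlates per-stimulus behavioral features with interneuron response
features (Bonferroni-corrected grid) and cross-correlates narrow- against
broad-waveform peri-stimulus rates to extract best lags.

Writes results/coupling/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_config

from callcode import coupling, io, units
from callcode.behavior import behavioral_features
from callcode.config import NARROW
from callcode.pipeline import session_features, session_psths
from callcode.synthgen import gen_paired_dataset


def main() -> None:
    cfg = analysis_config()
    out = RESULTS / "coupling"
    out.mkdir(parents=True, exist_ok=True)
    behavior_sessions, recordings = gen_paired_dataset(cfg.synth)

    beh = pd.concat(
        [behavioral_features(s.trials, s.responses, s.bird_id)
         for s in behavior_sessions],
        ignore_index=True,
    )
    neu_rows, lag_frames = [], []
    for rec in recordings:
        classes = {}
        for u in rec.units:
            wf = units.classify_waveform(u.mean_waveform, u.waveform_sample_rate_khz)
            if not wf.flagged:
                classes[u.unit_id] = wf.putative_class
        per_stim = session_psths(rec, bin_ms=cfg.bin_ms, by="stimulus_id")
        f = session_features(per_stim).rename(columns={"condition": "stimulus_id"})
        f["bird_id"] = rec.bird_id
        f["putative_class"] = f["unit_id"].map(classes)
        neu_rows.append(f[f["putative_class"] == NARROW])

        fine = session_psths(rec, bin_ms=1.0, smoothing="none",
                             window_ms=(-100.0, 400.0))
        narrow = {u: {c: z.rate_hz for c, z in per.items()}
                  for u, per in fine.items() if classes.get(u) == NARROW}
        broad = {u: {c: z.rate_hz for c, z in per.items()}
                 for u, per in fine.items()
                 if classes.get(u) not in (None, NARROW)}
        if narrow and broad:
            res = coupling.interneuron_pn_lags(narrow, broad,
                                               max_lag_ms=cfg.max_lag_ms)
            lag_frames.append(res.per_interneuron)

    neu = pd.concat(neu_rows, ignore_index=True)
    table = coupling.behavior_neural_correlation(beh, neu)
    io.write_tsv(table.to_frame(), out / "behavior_neural_correlation.tsv")
    print("behavior x interneuron correlation grid "
          f"(Bonferroni over {table.n_comparisons} cells):")
    for (b, n), cell in table.cells.items():
        mark = "*" if (cell.corrected_p == cell.corrected_p and cell.corrected_p < 0.05) else " "
        print(f"  {b} x {n}: r = {cell.r:+.2f}, corrected p = {cell.corrected_p:.3f} {mark}")

    lags = pd.concat(lag_frames, ignore_index=True)
    io.write_tsv(lags, out / "interneuron_lags.tsv")
    from scipy import stats

    rho, p = stats.spearmanr(lags["mean_coefficient"], lags["mean_best_lag_ms"])
    neg = (lags["mean_best_lag_ms"] < 0).mean()
    print(f"\n{len(lags)} interneurons: mean best lag "
          f"{lags['mean_best_lag_ms'].mean():.1f} ms, {neg:.0%} at negative lags "
          f"(narrow leads broad)")
    print(f"Spearman(coefficient, lag): rho = {rho:.2f}, p = {p:.3g}")
    (out / "summary.json").write_text(json.dumps(
        {"spearman_rho": float(rho), "spearman_p": float(p),
         "mean_best_lag_ms": float(lags["mean_best_lag_ms"].mean()),
         "frac_negative_lag": float(neg)}, indent=2))


if __name__ == "__main__":
    main()
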