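"""Per-unit spike processing: quality control, waveform classes, z-scored
PSTHs, responsiveness and response features.  Writes results/units/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_config

from callcode import io, units
from callcode.pipeline import session_features, session_psths
from callcode.synthgen import gen_paired_dataset


def main() -> None:
    cfg = analysis_config()
    out = RESULTS / "units"
    _, recordings = gen_paired_dataset(cfg.synth)

    reports, feats = [], []
    n_class_ok = 0
    n_classified = 0
    for rec in recordings:
        tab = pd.DataFrame([{"unit_id": u.unit_id, **u.qc} for u in rec.units])
        retained, report = units.qc_filter(tab, cfg.qc)
        reports.append(report)
        keep = set(retained["unit_id"])
        kept = [u for u in rec.units if u.unit_id in keep]
        cls = {}
        for u in kept:
            wf = units.classify_waveform(u.mean_waveform, u.waveform_sample_rate_khz)
            if wf.flagged:
                continue
            cls[u.unit_id] = wf.putative_class
            n_classified += 1
            n_class_ok += wf.putative_class == u.class_truth
        psths = session_psths(rec, bin_ms=cfg.bin_ms)
        f = session_features({u: p for u, p in psths.items() if u in cls})
        f["putative_class"] = f["unit_id"].map(cls)
        f["bird_id"] = rec.bird_id
        feats.append(f)

    report = pd.concat(reports, ignore_index=True)
    features = pd.concat(feats, ignore_index=True)
    io.write_tsv(report, out / "qc_report.tsv")
    io.write_tsv(features, out / "features.tsv")

    print(f"QC: retained {int(report['passed'].sum())}/{len(report)} units")
    print(f"waveform class vs generator truth: {n_class_ok}/{n_classified} correct")
    resp = features.groupby("putative_class")["responsive"].mean()
    print("responsive fraction by class:")
    print(resp.to_string())
    print("condition means (responsive units):")
    sel = features[features["responsive"]]
    print(sel.groupby(["putative_class", "condition"])[
        ["mean_z", "max_z", "response_duration_ms"]].mean().round(2).to_string())


if __name__ == "__main__":
    main()
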