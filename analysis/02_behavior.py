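"""Quantify vocal responses and classify playback familiarity from behavior.

Computes per-(bird, stimulus) features — peak response probability, median
response latency, latency variability — runs the paired familiar-vs-
unfamiliar signed-rank tests, and trains the permutation-calibrated
random-forest familiarity classifier.  Writes results/behavior/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_config

from callcode import io
from callcode.behavior import (
    BEHAVIOR_FEATURES,
    behavioral_features,
    classify_familiarity_behavior,
    paired_condition_test,
)
from callcode.config import FAMILIAR
from callcode.synthgen import gen_behavior_session


def main() -> None:
    cfg = analysis_config()
    out = RESULTS / "behavior"
    feats = pd.concat(
        [
            behavioral_features(s.trials, s.responses, s.bird_id,
                                bin_ms=cfg.histogram_bin_ms)
            for s in (gen_behavior_session(cfg.synth, b)
                      for b in range(cfg.synth.n_birds))
        ],
        ignore_index=True,
    )
    io.write_tsv(feats, out / "features.tsv")
    print(f"{len(feats)} (bird, stimulus) feature rows; familiar rows: "
          f"{int((feats['familiarity'] == FAMILIAR).sum())}")

    tests = {}
    for name in BEHAVIOR_FEATURES:
        stat, p, degenerate = paired_condition_test(feats, name)
        tests[name] = {"statistic": stat, "p": p, "degenerate": degenerate}
        print(f"  {name}: Wilcoxon signed-rank p = {p:.4f}")

    res = classify_familiarity_behavior(feats, cfg.clf_behavior)
    print(f"familiarity classification: {100 * res.mean_accuracy:.1f}% "
          f"(chance {100 * res.chance_level:.1f}%, null 95th "
          f"{100 * res.null_ci95:.1f}%, p = {res.p_value:.3f})")
    (out / "classifier.json").write_text(json.dumps(
        {"paired_tests": tests, "classifier": res.to_dict()}, indent=2))


if __name__ == "__main__":
    main()
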