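"""Cluster the playback clips by acoustic similarity (PCA on waveform
samples, silhouette-selected k-means).  Writes results/acoustics/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_config

from callcode import io
from callcode.acoustics import cluster_playbacks, preprocess_playback
from callcode.synthgen import gen_call_audio


def main() -> None:
    cfg = analysis_config()
    out = RESULTS / "acoustics"
    out.mkdir(parents=True, exist_ok=True)
    clips = [preprocess_playback(c) for c in gen_call_audio(cfg.synth, n_clusters=2)]
    res = cluster_playbacks(clips, seed=cfg.seed)
    coords = pd.DataFrame(res.coordinates)
    coords.insert(0, "stimulus_id", [c.stimulus_id for c in clips])
    coords.insert(1, "label", res.labels)
    coords.insert(2, "cluster_truth", [c.cluster_truth for c in clips])
    io.write_tsv(coords, out / "coordinates.tsv")
    (out / "summary.json").write_text(json.dumps(
        {"chosen_k": res.chosen_k,
         "silhouette": {str(k): v for k, v in res.silhouette.items()},
         "variance_explained": res.variance_explained.tolist()}, indent=2))
    print(f"{len(clips)} clips; retained {res.coordinates.shape[1]} PCs "
          f"({100 * res.variance_explained.sum():.1f}% variance)")
    print("silhouette by k:", {k: round(v, 3) for k, v in res.silhouette.items()})
    print(f"chosen k = {res.chosen_k}")


if __name__ == "__main__":
    main()
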