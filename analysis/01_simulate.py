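"""Generate the synthetic playback experiment: behavioral sessions, paired
head-fixed recordings and call-audio clips, all from one seed.

Writes the raw tables under results/data/ and prints what was produced.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, analysis_config

from callcode import io
from callcode.synthgen import gen_call_audio, gen_paired_dataset


def main() -> None:
    cfg = analysis_config()
    out = RESULTS / "data"
    behavior, recordings = gen_paired_dataset(cfg.synth)
    n_files = 0
    for s in behavior:
        n_files += len(io.write_behavior_session(s, out / "behavior"))
    for r in recordings:
        n_files += len(io.write_recording_session(r, out / "ephys"))
    clips = gen_call_audio(cfg.synth, n_clusters=2)
    for c in clips:
        io.write_wav(c, out / "audio" / f"{c.stimulus_id}.wav")
    n_trials = sum(len(s.trials) for s in behavior)
    n_resp = sum(len(s.responses) for s in behavior)
    n_units = sum(len(r.units) for r in recordings)
    print(f"simulated {len(behavior)} birds: {n_trials} playback trials, "
          f"{n_resp} call responses ({n_resp / n_trials:.1%} answered)")
    print(f"recordings: {len(recordings)} sessions, {n_units} units")
    print(f"audio: {len(clips)} clips in 2 clusters")
    print(f"wrote {n_files + len(clips)} files under {out}")


if __name__ == "__main__":
    main()
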