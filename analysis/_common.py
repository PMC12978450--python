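"""Shared configuration for the numbered analysis scripts.

One seeded configuration drives every step so each script can regenerate the
same synthetic experiment deterministically without re-reading intermediate
files.  Sizes are moderate so the full sequence runs in a few minutes.
"""

from pathlib import Path

from callcode import ClassifierConfig, RunConfig, SynthConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def analysis_config(seed: int = 2) -> RunConfig:
    synth = SynthConfig(
        seed=seed,
        n_narrow=10,
        n_broad=18,
        salience_sd=0.25,
    )
    return RunConfig(
        seed=seed,
        out_dir=str(RESULTS / "pipeline"),
        synth=synth,
        clf_behavior=ClassifierConfig(n_iter=200, test_frac=0.5, n_perm=200,
                                      runs_per_perm=5, n_trees=50),
        clf_neural=ClassifierConfig(n_iter=200, test_frac=0.1, n_perm=200,
                                    runs_per_perm=5),
    )
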