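"""Shared test utilities: null-effect configurations and small datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd

from callcode import SynthConfig
from callcode.config import BROAD, FAMILIAR, NARROW, UNFAMILIAR


def null_synth_config(seed: int, **kwargs) -> SynthConfig:
    """Study-scale config with every familiarity effect zeroed.

    Conditions become exchangeable: equal response probabilities and latency
    distributions, equal evoked gains and sustained decays for both classes.
    """
    cfg = SynthConfig(seed=seed, **kwargs)
    cfg.resp_prob = {FAMILIAR: 0.10, UNFAMILIAR: 0.10}
    cfg.latency_mean_ms = {FAMILIAR: 330.0, UNFAMILIAR: 330.0}
    cfg.latency_sd_ms = {FAMILIAR: 250.0, UNFAMILIAR: 250.0}
    cfg.evoked_gain[NARROW] = {FAMILIAR: 0.7, UNFAMILIAR: 0.7}
    cfg.evoked_gain[BROAD] = {FAMILIAR: 1.6, UNFAMILIAR: 1.6}
    cfg.sustain_tau_ms[NARROW] = {FAMILIAR: 150.0, UNFAMILIAR: 150.0}
    cfg.sustain_tau_ms[BROAD] = {FAMILIAR: 150.0, UNFAMILIAR: 150.0}
    return cfg


def toy_trials(n: int = 10, period_s: float = 1.0, dur_s: float = 0.15) -> pd.DataFrame:
    onsets = np.arange(n) * period_s
    return pd.DataFrame(
        {
            "trial_id": [f"t{i}" for i in range(n)],
            "stimulus_id": ["s0"] * n,
            "familiarity": [FAMILIAR] * n,
            "onset_s": onsets,
            "offset_s": onsets + dur_s,
        }
    )


def toy_responses(latencies_ms: dict[int, float], trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for i, lat in latencies_ms.items():
        on = trials["onset_s"].iloc[i] + lat / 1000.0
        rows.append({"trial_id": trials["trial_id"].iloc[i], "onset_s": on, "offset_s": on + 0.1})
    return pd.DataFrame(rows, columns=["trial_id", "onset_s", "offset_s"])
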