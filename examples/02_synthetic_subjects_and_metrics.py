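"""Simulate control / PD / ET subjects and extract the eight epoch metrics.

Each subject tracks freshly generated target paths; the cursor model adds
tremor, lag, slowing and noise according to the subject profile.  Metrics
are computed on 1-second non-overlapping epochs; the printed group means
show which motor features each profile expresses.
"""

import numpy as np
import pandas as pd

from motortrace import (
    CONTROL_PROFILE,
    ET_PROFILE,
    PD_PROFILE,
    PathConfig,
    compute_metric_table,
    simulate_session,
)
from motortrace.metrics import METRIC_NAMES

cfg = PathConfig(n_trials=4)  # shortened session for the demo

tables = []
for i, profile in enumerate((CONTROL_PROFILE, PD_PROFILE, ET_PROFILE)):
    session = simulate_session(
        profile, cfg, np.random.default_rng(100 + i), f"{profile.label}_demo"
    )
    tables.append(compute_metric_table(session))
table = pd.concat(tables, ignore_index=True)

means = table.groupby("group")[list(METRIC_NAMES)].mean().round(4)
print(means.T)
print()
print("Reading the columns: the ET subject shows a large 'tremor' (the 0.35 cm")
print("injected 6 Hz oscillation) with everything else control-like, while the")
print("PD subject spreads dysfunction across distance, slowness, speed and")
print("pressure -- the heterogeneity the severity score has to aggregate.")
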