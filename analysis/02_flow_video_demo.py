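#!/usr/bin/env python
"""Video-tier demonstration of the optical-flow stage.

Renders a micro experiment (4 trials, 300 frames, 64 x 64 px) of ellipse
fish on a correlated random walk, runs dense Lucas-Kanade flow over every
frame pair, and shows that (i) the flow magnitude is zero without motion,
(ii) turbidity (exponential contrast attenuation with distance) lowers the
mean magnitude on identical motion paths, and (iii) warming raises it via
faster swimming.  Writes per-trial magnitude series under
results/video_demo/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS

from preyflow import synthetic
from preyflow.flow import magnitude_series, write_series_csv
from preyflow.synthetic import ArenaConfig

out = RESULTS / "video_demo"
out.mkdir(parents=True, exist_ok=True)

cfg = ArenaConfig(frame_size=(64, 64), n_frames=300, n_fish=4, seed=0)
rows = []
for treatment in synthetic.TREATMENTS:
    frames = synthetic.simulate_trial_video(cfg, treatment)
    series = magnitude_series(frames, trial_id=treatment)
    write_series_csv(series, out / f"{treatment}.csv")
    rows.append(
        {
            "treatment": treatment,
            "mean_magnitude": series.values.mean(),
            "p95_magnitude": np.percentile(series.values, 95),
        }
    )

table = pd.DataFrame(rows)
table.to_csv(out / "summary.csv", index=False)
print(table.to_string(index=False))
print()
m = table.set_index("treatment")["mean_magnitude"]
print(f"Turbidity lowers mean flow magnitude: {m['turbid']:.4f} < {m['control']:.4f}"
      f" -> {'yes' if m['turbid'] < m['control'] else 'NO'}")
print(f"Warming raises mean flow magnitude:   {m['warm']:.4f} > {m['control']:.4f}"
      f" -> {'yes' if m['warm'] > m['control'] else 'NO'}")
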