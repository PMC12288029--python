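#!/usr/bin/env python
"""GLMM/AICc model comparison for the four per-trial responses.

Reads metrics from results/run/ (run 01 and 03 first), fits the eight
candidate models (null + seven single-hypothesis alternatives, tank random
intercept, family matched to each response) at every percentile level, and
writes AICc ranking tables.  Prints the best-supported model per response x
level and the direction of the treatment effects.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, run_config

from preyflow.pipeline import stage_fit

cfg = run_config()
if not (RUN_DIR / "metrics.csv").exists():
    raise SystemExit("run analysis/01 and 03 first")
stage_fit(cfg)

rows = []
for path in sorted((RUN_DIR / "rankings").glob("*.csv")):
    table = pd.read_csv(path)
    kind, level = path.stem.rsplit("_p", 1)
    best = table.iloc[0]
    null_delta = table.set_index("model").loc["Null", "delta_aicc"]
    rows.append({"response": kind, "level": float(level), "best_model": best["model"],
                 "null_delta_aicc": round(null_delta, 1)})
summary = pd.DataFrame(rows).sort_values(["response", "level"], ascending=[True, False])
print(summary.to_string(index=False))

coef = pd.read_csv(RUN_DIR / "coefficients.csv")
turb = coef[(coef["model"] == "Turbidity") & (coef["term"] == "turb")]
temp = coef[(coef["model"] == "Temperature") & (coef["term"] == "temp")]
print("\nTurbidity coefficients (Turbidity-only model, link scale):")
print(turb[["response", "percentile_level", "estimate", "se"]].round(3).to_string(index=False))
print("\nTemperature coefficients (Temperature-only model, link scale):")
print(temp[["response", "percentile_level", "estimate", "se"]].round(3).to_string(index=False))
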