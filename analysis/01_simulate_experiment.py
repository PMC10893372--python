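#!/usr/bin/env python
"""Generate a synthetic eight-treatment hydroponic Cd experiment.

Writes the long-format plants table, the per-container solution states and
the generating ground truth under results/synthetic/. These files feed the
later pipeline stages and mirror the structure of the real experiment:
3 L of 2.25 mg/L Cd per container, three seedlings of which two are
analysed, hydroponic Fe raising both uptake and the shoot Cd fraction.
"""

import argparse
import json
from pathlib import Path

from cdisoflux.synthetic import SimConfig, simulate_experiment

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/synthetic"))
args = parser.parse_args()

cfg = SimConfig()
res = simulate_experiment(cfg, seed=args.seed)
args.out.mkdir(parents=True, exist_ok=True)
res.plants.to_csv(args.out / "plants.csv", index=False, float_format="%.12g")
res.solutions.to_csv(args.out / "solutions.csv", index=False, float_format="%.12g")
(args.out / "truth.json").write_text(json.dumps(res.truth, indent=2, sort_keys=True) + "\n")

per_plant = [p["total_cd_ug"] for t in res.truth["treatments"] for p in t["plants"]]
print(f"simulated {len(res.truth['treatments'])} treatments, "
      f"{len(per_plant)} plants ({len(res.plants)} organ measurements analysed)")
print(f"per-plant total Cd: {min(per_plant):.0f}-{max(per_plant):.0f} ug "
      f"(mean {sum(per_plant)/len(per_plant):.0f} ug)")
print(f"wrote plants.csv, solutions.csv, truth.json to {args.out}")
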