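#!/usr/bin/env python
"""Generate the synthetic Disko Bay stand-in dataset.

Writes the observation and assemblage tables for the bundled fixture (six
species × warm/cold, published means/SDs/n, assemblage totals 613 and 680)
to results/data/. Downstream scripts read these files.
"""

import argparse
from pathlib import Path

from paleosize import synth
from paleosize.io_model import write_assemblage, write_observations

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
args = parser.parse_args()

args.out_dir.mkdir(parents=True, exist_ok=True)
config = synth.default_config(seed=args.seed)
observations = synth.generate_observations(config)
assemblage = synth.generate_assemblage(config)
write_observations(observations, args.out_dir / "obs.csv")
write_assemblage(assemblage, args.out_dir / "assemblage.csv")

print(f"seed {args.seed}: wrote {len(observations)} observations "
      f"({sum(s.n_measured for s in config.specs)} expected) and "
      f"{len(assemblage)} assemblage rows to {args.out_dir}/")
for period in ("warm", "cold"):
    total = sum(a.count for a in assemblage if a.period == period)
    print(f"  {period}: {total} counted cysts")
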