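#!/usr/bin/env python
"""Measured sizes versus literature ranges and midpoints.

Derives diameter ranges for the length×width taxa, compares measured
means and total size ranges to the literature table, and computes the
literature-based interspecific community mean per period. Writes
litcmp.csv under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from paleosize import datasets
from paleosize.io_model import read_assemblage, read_observations
from paleosize.decomp import species_weights
from paleosize.litcompare import compare_species, literature_community_mean
from paleosize.report import summarize

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

observations = read_observations(args.data_dir / "obs.csv")
assemblage = read_assemblage(args.data_dir / "assemblage.csv")
entries = datasets.load_default_literature()
summaries = summarize(observations)

rows = []
for entry in entries:
    values = [o.diameter for o in observations if o.species == entry.species]
    c = compare_species(summaries, (min(values), max(values)), entry)
    rows.append((c.species, *c.literature_range, c.midpoint,
                 round(c.measured_range[0], 1), round(c.measured_range[1], 1),
                 ";".join(sorted(c.flags)) or "-"))
table = pd.DataFrame(
    rows, columns=["species", "lit_min", "lit_max", "midpoint",
                   "measured_min", "measured_max", "flags"],
)
table.to_csv(args.out_dir / "litcmp.csv", index=False)
print(table.to_string(index=False))

print("\nliterature-based interspecific community mean:")
for period in ("warm", "cold"):
    weights = species_weights(assemblage, period, {e.species for e in entries})
    cm = literature_community_mean(entries, weights)
    print(f"  {period}: {cm.mean:.2f} um (se {cm.se:.2f})")
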