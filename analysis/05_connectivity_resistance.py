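#!/usr/bin/env python
"""Circuit-theory connectivity on a synthetic friction landscape.

Builds a friction raster over the simulated pond landscape (wetland cells
cheap, open matrix expensive, a high-friction ridge between the regions),
computes pairwise effective resistances between a sample of ponds, and
summarizes them by region: the global mean resistance exceeds each
within-region mean, and the between-region structure mirrors the Hanski
index's near-zero cross-region kernel weights.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pondshift.connectivity import (DEFAULT_ALPHA, effective_resistance,
                                    hanski_index, region_resistance_summary)
from pondshift.core_io import FrictionRaster
from pondshift.synthetic_data import generate_landscape

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

land = generate_landscape(seed=0)
cellsize = 100.0
x0, y0 = land.x.min() - cellsize, land.y.min() - cellsize
nc = int((land.x.max() - x0) / cellsize) + 2
nr = int((land.y.max() - y0) / cellsize) + 2

rng = np.random.default_rng(0)
friction = np.full((nr, nc), 10.0)          # open matrix
friction[rng.random((nr, nc)) < 0.4] = 3.0  # forest patches
mid_col = int((land.x.mean() - x0) / cellsize)
friction[:, mid_col - 1:mid_col + 2] = 100.0   # central ridge ("slope")

cells = {}
for pid, pond in land.iterrows():
    r = nr - 1 - int((pond.y - y0) / cellsize)   # row 0 is north
    c = int((pond.x - x0) / cellsize)
    friction[r, c] = 1.0                         # wetland cells
    cells[pid] = (r, c)

raster = FrictionRaster(values=friction, cellsize=cellsize)
sample = list(land.groupby("region").head(6).index)
res = effective_resistance(raster, {p: cells[p] for p in sample})
summary = region_resistance_summary(res, land.loc[sample, "region"])
print("pairwise effective resistance summary "
      f"(friction wetland=1, forest=3, open=10, ridge=100):")
print(summary.round(3).to_string(index=False))
g = summary.set_index("region")
print("\nglobal mean exceeds each within-region mean: "
      f"{bool((g.loc['global', 'mean'] > g.drop('global')['mean']).all())}")

pops = pd.Series(1000.0, index=land.index)
hk = hanski_index(land, pops, DEFAULT_ALPHA)
print(f"\nHanski index (uniform populations of 1000): within-region mean "
      f"{hk.mean():.0f}; kernel weight across the ~2 km region gap "
      f"is ~{np.exp(-DEFAULT_ALPHA * 2000):.1e}, so the regions are "
      "effectively independent for a 125 m dispersal scale.")

summary.to_csv(OUT / "resistance_summary.csv", index=False)
res.resistance.to_csv(OUT / "resistance_matrix.csv")
print(f"\nwrote {OUT}/resistance_summary.csv")
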