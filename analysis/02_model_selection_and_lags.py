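#!/usr/bin/env python
"""Information-theoretic ranking of d-a models and density/occupancy lags.

Re-derives the AICc ranking of the constrained distribution-abundance
candidate models from their published residual sums of squares, converts
the ln-density regimes back to arithmetic means, and cross-correlates ln
density against occupancy to show that density leads occupancy by a year.
"""

from pathlib import Path

import numpy as np

from pondshift.da_models import aicc_rank
from pondshift.refdata import (CHORUS_FROG_LN_DENSITY,
                               CHORUS_FROG_OCCUPANCY,
                               CONSTRAINED_DA_MODEL_TABLE)
from pondshift.timeseries_stats import cross_correlation

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

tab = aicc_rank(CONSTRAINED_DA_MODEL_TABLE)
print("AICc ranking of the constrained d-a candidate models:")
print(tab[["family", "K", "rss", "aic", "aicc", "delta", "rel_lik",
           "weight", "evidence_ratio"]].round(3).to_string(index=False))
best = tab.iloc[0]
print(f"\nBest-supported model: {best['family']} "
      f"(weight {best['weight']:.3f}); the two-level step model is the "
      f"only serious competitor (evidence ratio "
      f"{tab.set_index('family').loc['seg_horizontal_horizontal', 'evidence_ratio']:.2f}).")

dens = np.exp(CHORUS_FROG_LN_DENSITY)
print("\nBack-transformed mean larval densities (individuals/m^2):")
print(f"  1996-1999: {dens.loc[1996:1999].mean():.1f}")
print(f"  2000-2009: {dens.loc[2000:2009].mean():.1f}")
print(f"  2010:      {dens.loc[2010]:.1f}")

cc = cross_correlation(CHORUS_FROG_LN_DENSITY, CHORUS_FROG_OCCUPANCY,
                       max_lag=3)
print("\nCross-correlation of ln density (leading at positive lags) "
      "with occupancy:")
print(cc.round(3).to_string(index=False))
peak = cc.loc[cc["r"].idxmax()]
print(f"\nThe correlation peaks with density leading by {int(peak['lag'])} "
      f"year (r = {peak['r']:.2f}, p = {peak['p']:.3f}): local density "
      "shifts precede the occupancy response.")

tab.to_csv(OUT / "model_selection.csv", index=False)
cc.to_csv(OUT / "cross_correlation.csv", index=False)
print(f"\nwrote {OUT}/model_selection.csv and cross_correlation.csv")
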