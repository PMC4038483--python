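#!/usr/bin/env python
"""Full pipeline on the synthetic metacommunity: availability, d-a fits,
regime shifts, tracking and connectivity in one machine-readable report.

Runs every stage on the canned scenario (seed 0) and prints the headline
numbers: the interspecific distribution-abundance points, the best d-a
model per axis, the focal species' confirmed regime shifts, and the
occupied-vs-unoccupied connectivity comparison.
"""

from pathlib import Path

import pandas as pd

from pondshift.pipeline import AnalysisConfig, run_all

OUT = Path(__file__).resolve().parent.parent / "results" / "pipeline"
report = run_all(AnalysisConfig(synthetic_seed=0, seed=0, out=str(OUT)))

pts = pd.DataFrame(report["interspecific"]["points"])
print("interspecific d-a points (per species):")
print(pts.round(2).to_string(index=False))
r = pts["mean_density"].corr(pts["mean_occupancy"])
print(f"\ndensity-occupancy correlation across species: r = {r:.2f}")

for axis in ("fit_raw", "fit_constrained"):
    if axis in report["interspecific"]:
        fit = pd.DataFrame(report["interspecific"][axis])
        print(f"\n{axis}: best model = {fit.iloc[0]['family']} "
              f"(weight {fit.iloc[0]['weight']:.2f})")

focal = report["per_species"]["PTR"]
shifts = focal["regime_shifts"]
print(f"\nfocal regime shifts: years {shifts['shift_years']}, "
      f"RSI {[round(v, 3) for v in shifts['rsi']]}, "
      f"regime means {[round(m, 1) for m in shifts['regime_means']]}")
print(f"focal availability tracking: r = {focal['tracking']['r']}, "
      f"mean occupied:available ratio = "
      f"{round(focal['tracking']['mean_ratio'], 2)}")

conn = report["connectivity"]["PTR"]
print(f"\nconnectivity, occupied vs unoccupied ponds (final year): "
      f"t({conn['df']}) = {conn['t']:.2f}, p = {conn['p']:.3f}, "
      f"means ratio = {conn['means_ratio']:.2f}")
print(f"\nwrote {OUT}/report.json")
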