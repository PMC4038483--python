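"""Reference monitoring data for the E. S. George Reserve (ESGR) chorus frog.

Transcribed summary series from the published 15-year (1996-2010) amphibian
monitoring program on the ESGR, Michigan: annual pond-occupancy counts and
ln mean larval densities for *Pseudacris triseriata*, the model-selection
summary for the constrained interspecific distribution-abundance relationship,
and the pond-category occupancy frequencies used by the weighted-suitability
estimator.  These are the canonical desk-checkable inputs for the regime-shift
and information-theoretic machinery in this package.
"""

from __future__ import annotations

import pandas as pd

#: Years covered by the monitoring series.
YEARS = list(range(1996, 2011))

#: Number of ponds occupied by the chorus frog each year.
CHORUS_FROG_OCCUPANCY = pd.Series(
    [5, 6, 3, 3, 6, 21, 20, 15, 17, 17, 19, 20, 21, 21, 8],
    index=YEARS, name="occupancy", dtype=float,
)

#: ln of mean larval density (individuals/m^2) in occupied ponds each year.
CHORUS_FROG_LN_DENSITY = pd.Series(
    [0.262, 0.034, 0.693, 0.949, 1.966, 1.030, 2.055, 1.351, 0.095,
     1.133, 1.165, 1.672, 1.655, 1.115, 0.523],
    index=YEARS, name="ln_density",
)

#: Model-selection summary for the constrained interspecific d-a relationship:
#: candidate family, parameter count K (error variance included) and residual
#: sum of squares, all fit to the same 13 species.
CONSTRAINED_DA_MODEL_TABLE = pd.DataFrame(
    [
        ("saturating", 3, 13, 0.16),
        ("seg_horizontal_horizontal", 4, 13, 0.13),
        ("linear", 3, 13, 0.32),
        ("seg_sloping_horizontal", 5, 13, 0.15),
        ("mean", 2, 13, 0.58),
        ("seg_sloping_sloping", 6, 13, 0.16),
    ],
    columns=["family", "K", "n", "rss"],
)

#: Chorus-frog occupancy frequency by pond category during the high-abundance
#: period, used to weight category counts into an expected number of suitable
#: ponds: open canopy ponds that dried the previous fall, open ponds that did
#: not dry, and closed-canopy ponds.
SUITABILITY_FREQS = {
    "open_dried": 0.93,
    "open_wet": 0.40,
    "closed": 0.32,
}

#: Mean larval densities (individuals/m^2) observed in the same three pond
#: categories during the high-abundance period.
CATEGORY_DENSITIES = {
    "open_dried": 6.2,
    "open_wet": 3.0,
    "closed": 0.9,
}
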