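"""Habitat availability and constrained occupancy.

A pond can only count against a species' occupancy if the species could
plausibly breed there that year.  Availability is estimated from pond
condition — the maximum area the pond reaches during a 30-day window around
the species' breeding peak, divided by the maximum area ever recorded for
that pond — and from the cumulative ("habitable") set of ponds in which the
species has ever been recorded.  Constrained occupancy is then occupied
ponds over the available-and-habitable set; values above 1 are meaningful
(mass effects can hold a species in more ponds than are estimated available)
and are flagged rather than clipped.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "pond_condition", "available_ponds", "habitable_set",
    "constrained_occupancy", "weighted_suitability", "availability_series",
    "CONDITION_THRESHOLD",
]

CONDITION_THRESHOLD = 0.30   # strict: condition must exceed this


def pond_condition(hydro: pd.DataFrame, ponds: pd.DataFrame,
                   stat: str = "max") -> pd.DataFrame:
    """Per pond-year condition: window-max area over max area ever, in [0, 1].

    ``hydro`` must carry per pond-year area observations for the breeding
    window (column ``area``; multiple rows per pond-year are reduced by
    ``stat``, the window maximum by definition — a ``mean`` switch exists
    for sensitivity checks).  Missing observations yield NaN condition.
    """
    if stat not in ("max", "mean"):
        raise ValueError("stat must be 'max' or 'mean'")
    agg = hydro.groupby(["pond_id", "year"])["area"].agg(stat).reset_index()
    agg = agg.merge(ponds["max_area_ever"].rename("max_ever"),
                    left_on="pond_id", right_index=True, how="left")
    if agg["max_ever"].isna().any():
        bad = agg.loc[agg["max_ever"].isna(), "pond_id"].unique()
        raise ValueError(f"ponds missing from pond table: {list(bad)[:5]}")
    agg["condition"] = (agg["area"] / agg["max_ever"]).clip(0.0, 1.0)
    return agg[["pond_id", "year", "condition"]]


def available_ponds(conditions: pd.DataFrame, year: int,
                    dried_before_sampling: set | None = None,
                    threshold: float = CONDITION_THRESHOLD) -> set:
    """Ponds with condition strictly above the threshold that did not dry
    before sampling.  Condition at exactly the threshold is excluded."""
    sub = conditions[conditions["year"] == year]
    ok = sub.loc[sub["condition"] > threshold, "pond_id"]
    out = set(ok)
    if dried_before_sampling:
        out -= set(dried_before_sampling)
    return out


def habitable_set(survey: pd.DataFrame, species_id: str):
    """Cumulative set of ponds in which the species was ever recorded.

    Returns (final set, accumulation curve as a Series indexed by year).
    The curve is monotone nondecreasing by construction; for most species
    it approaches an asymptote after 3-5 years of monitoring.
    """
    sp = survey[(survey["species_id"] == species_id) & (survey["density"] > 0)]
    years = sorted(survey["year"].unique())
    if sp.empty:
        warnings.warn(f"species {species_id!r} never present; habitable set empty")
        return set(), pd.Series([0] * len(years), index=years, dtype=int)
    seen: set = set()
    counts = []
    for y in years:
        seen |= set(sp.loc[sp["year"] == y, "pond_id"])
        counts.append(len(seen))
    return seen, pd.Series(counts, index=years, name="cumulative_ponds")


def constrained_occupancy(occupied: set, available: set, habitable: set):
    """|occupied| / |available ∩ habitable|; NaN when the denominator is 0.

    Returns (fraction, flag) where flag marks denominator-0 ('undefined')
    or occupancy above availability ('exceeds_availability').
    """
    denom = len(available & habitable)
    if denom == 0:
        return float("nan"), "undefined"
    frac = len(occupied) / denom
    return frac, ("exceeds_availability" if frac > 1 else "")


def availability_series(survey: pd.DataFrame, conditions: pd.DataFrame,
                        species_id: str,
                        dried_before_sampling: dict | None = None,
                        threshold: float = CONDITION_THRESHOLD) -> pd.DataFrame:
    """Year-by-year available/occupied/habitable sets and constrained occupancy.

    ``dried_before_sampling`` maps year -> set of ponds that dried before the
    species' sampling date that year (config input; empty by default).
    """
    collapsed = survey[survey["species_id"] == species_id]
    habitable, curve = habitable_set(survey, species_id)
    dried = dried_before_sampling or {}
    rows = []
    for year in sorted(survey["year"].unique()):
        avail = available_ponds(conditions, year, dried.get(year), threshold)
        occ = set(collapsed.loc[(collapsed["year"] == year)
                                & (collapsed["density"] > 0), "pond_id"])
        frac, flag = constrained_occupancy(occ, avail, habitable)
        rows.append({"species_id": species_id, "year": year,
                     "n_available": len(avail & habitable),
                     "n_occupied": len(occ),
                     "constrained_occupancy": frac, "flag": flag})
    out = pd.DataFrame(rows)
    out.attrs["habitable_set"] = habitable
    out.attrs["accumulation_curve"] = curve
    return out


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def weighted_suitability(category_counts: dict, category_freqs: dict) -> int:
    """Expected number of suitable ponds from category counts and occupancy
    frequencies: round(sum count_c * freq_c), half away from zero."""
    if set(category_counts) != set(category_freqs):
        raise ValueError(
            f"category keys differ: {sorted(category_counts)} vs "
            f"{sorted(category_freqs)}")
    for c, f in category_freqs.items():
        if not 0 <= f <= 1:
            raise ValueError(f"frequency for {c!r} outside [0, 1]")
    total = sum(category_counts[c] * category_freqs[c] for c in category_counts)
    return _round_half_away(total)
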