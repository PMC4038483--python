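"""Lagged cross-correlations and availability-tracking diagnostics.

Lag convention: a POSITIVE lag means the FIRST series leads (series ``a`` at
year t is paired with series ``b`` at year t + lag).  This is printed in the
output to avoid the classic cross-correlation sign trap.  Correlations are
plain Pearson on overlapping pairs, with no detrending; p-values come from
the t transform of r with n-2 degrees of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["cross_correlation", "tracking_metrics", "intraspecific_da"]


def _pearson(a: np.ndarray, b: np.ndarray):
    n = len(a)
    if n < 3 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), n


def cross_correlation(a: pd.Series, b: pd.Series, max_lag: int = 3,
                      min_overlap: int = 3) -> pd.DataFrame:
    """Pearson r between ``a`` (leading at positive lags) and ``b`` per lag.

    Series are aligned on their (year) index; at lag k the pairs are
    ``(a[t], b[t+k])``.  Lags with fewer than ``min_overlap`` pairs are
    omitted.
    """
    rows = []
    for lag in range(-max_lag, max_lag + 1):
        shifted = b.copy()
        shifted.index = shifted.index - lag
        joined = pd.concat([a, shifted], axis=1, join="inner").dropna()
        if len(joined) < min_overlap:
            continue
        r, p, n = _pearson(joined.iloc[:, 0].to_numpy(),
                           joined.iloc[:, 1].to_numpy())
        rows.append({"lag": lag, "r": r, "p": p, "n": n})
    out = pd.DataFrame(rows, columns=["lag", "r", "p", "n"])
    out.attrs["lag_convention"] = "positive lag = first series leads"
    return out


def tracking_metrics(occupied: pd.Series, available: pd.Series) -> dict:
    """How closely occupancy tracks availability: lag-0 Pearson r plus the
    mean yearly occupied:available ratio.  Years with zero availability are
    skipped with a warning."""
    joined = pd.concat([occupied.rename("occ"), available.rename("avail")],
                       axis=1, join="inner").dropna()
    zero = joined["avail"] == 0
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} year(s) with zero availability")
        joined = joined[~zero]
    if joined.empty:
        return {"r": np.nan, "p": np.nan, "mean_ratio": np.nan, "n_years": 0}
    r, p, n = _pearson(joined["occ"].to_numpy(dtype=float),
                       joined["avail"].to_numpy(dtype=float))
    if np.isnan(r) and (joined["occ"] == joined["avail"]).all():
        r, p = 1.0, 0.0   # identical (possibly constant) series track perfectly
    ratio = float((joined["occ"] / joined["avail"]).mean())
    return {"r": r, "p": p, "mean_ratio": ratio, "n_years": int(len(joined))}


def intraspecific_da(summaries: pd.DataFrame, *, region: str | None = None,
                     exclude_outliers: bool = False, min_years: int = 6,
                     n_boot: int = 0, seed: int | None = None):
    """Within-species distribution-abundance model suite across years.

    ``summaries`` needs one row per year with columns
    ``mean_density_occupied`` (x) and ``n_occupied`` (y), plus optionally
    ``region``.  With ``exclude_outliers`` points with Cook's distance above
    4/n under the linear fit are dropped before refitting (the rule used to
    screen anomalous survey years).  Returns the ranked model table with the
    fitted models in ``attrs['models']``.
    """
    from .da_models import aicc_rank, cooks_outliers, fit_all

    df = summaries
    if region is not None:
        df = df[df["region"] == region]
    df = df.dropna(subset=["mean_density_occupied", "n_occupied"])
    if len(df) < min_years:
        raise ValueError(f"need >= {min_years} years, got {len(df)}")
    x = df["mean_density_occupied"].to_numpy(dtype=float)
    y = df["n_occupied"].to_numpy(dtype=float)
    dropped = []
    if exclude_outliers:
        d, flagged, cut = cooks_outliers(x, y)
        if len(flagged):
            dropped = list(np.asarray(df.index)[flagged])
            keep = np.setdiff1d(np.arange(len(x)), flagged)
            x, y = x[keep], y[keep]
    models = fit_all(x, y, n_boot=n_boot, seed=seed)
    tab = aicc_rank(models)
    tab.attrs["models"] = {m.family: m for m in models}
    tab.attrs["dropped_outliers"] = dropped
    return tab
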