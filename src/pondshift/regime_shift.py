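"""Sequential t-test regime-shift detection (STARS) with the Regime Shift Index.

The detector scans an annual series for abrupt changes in mean ("regime
shifts") by sequentially testing whether each new observation is consistent
with the running mean of the current regime.  A value falling outside the
critical band ``mean ± diff`` opens a candidate shift; the candidate is
confirmed or rejected by the signed, normalized cumulative excursion of the
following years beyond the critical level — the Regime Shift Index (RSI).
The method does not lose power when a change point sits near the end of the
series: a candidate in the final years is judged on the values available.

Conventions (chosen to reproduce the published reference tables for the ESGR
chorus frog, see :mod:`pondshift.refdata` and docs/methods.md):

* ``sigma_l**2`` is the mean sample variance over all running ``l``-year
  windows of the full series.
* ``diff = t_{1-alpha/2, 2l-2} * sqrt(2*sigma_l**2/l)`` (two-tailed t).
* Regime means are Huber-weighted: anomalies beyond ``huber`` sigma are
  downweighted by ``huber/|z|``.  Weights are recomputed from the arithmetic
  mean in a fixed number of reweighting passes (default 2).
* RSI is the Huber-weighted mean of the anomalies of the testing window
  (up to ``l`` years from the candidate) relative to the critical level,
  in ``sigma_l`` units, signed by shift direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StarsParams", "RegimeShiftResult", "stars", "stars_sweep"]


@dataclass(frozen=True)
class StarsParams:
    """Tuning parameters for the sequential t-test scan.

    Parameters
    ----------
    cutoff : int
        Expected minimum regime length ``l`` in years.  Regimes at least
        this long are always detected; shorter ones only if strong.
    alpha : float
        Two-tailed significance level of the t-test defining the critical
        band between regimes.
    huber : float
        Huber weight parameter: anomalies beyond ``huber`` sigma contribute
        with weight ``huber/|z|`` to regime means and to the RSI.
    mean_passes : int
        Number of reweighting passes when computing weighted regime means.
    """

    cutoff: int = 4
    alpha: float = 0.05
    huber: float = 1.0
    mean_passes: int = 2

    def __post_init__(self) -> None:
        if self.cutoff < 2:
            raise ValueError("cutoff length must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.huber <= 0:
            raise ValueError("huber parameter must be positive")


@dataclass
class RegimeShiftResult:
    """Per-year regime table plus confirmed-shift summaries.

    ``table`` has one row per year: value, signed RSI (0 for years that do
    not open a confirmed shift), the (unweighted) mean and length of the
    regime the year belongs to, and the Welch t-test p-value between the
    new and the preceding regime in the shift year ("confidence").
    """

    table: pd.DataFrame
    shift_years: list = field(default_factory=list)
    sigma_l: float = np.nan
    diff: float = np.nan
    params: StarsParams | None = None

    @property
    def regime_means(self) -> list[float]:
        return list(self.table.groupby("regime", sort=True)["value"].mean())

    @property
    def regime_lengths(self) -> list[int]:
        return list(self.table.groupby("regime", sort=True)["value"].size())


def _huber_weights(z: np.ndarray, h: float) -> np.ndarray:
    az = np.abs(z)
    with np.errstate(divide="ignore"):
        return np.where(az > h, h / np.maximum(az, 1e-300), 1.0)


def _weighted_regime_mean(values: np.ndarray, sigma: float, h: float,
                          passes: int) -> float:
    """Huber-weighted regime mean, starting from the arithmetic mean."""
    m = float(np.mean(values))
    if sigma == 0:
        return m
    for _ in range(passes):
        w = _huber_weights((values - m) / sigma, h)
        m = float(np.sum(w * values) / np.sum(w))
    return m


def running_window_sigma(values: np.ndarray, cutoff: int) -> float:
    """sigma_l: sqrt of the mean sample variance over running l-windows."""
    n = len(values)
    if n < cutoff:
        raise ValueError(f"series of length {n} shorter than cutoff {cutoff}")
    var = [np.var(values[i:i + cutoff], ddof=1) for i in range(n - cutoff + 1)]
    return float(np.sqrt(np.mean(var)))


def stars(series: pd.Series, params: StarsParams | None = None) -> RegimeShiftResult:
    """Run the sequential t-test regime-shift scan on a yearly series.

    Parameters
    ----------
    series : pandas.Series
        Values indexed by year (any sorted, equally spaced index works).
        Missing values are a hard error; interpolate first if needed.
    params : StarsParams, optional
        Scan parameters; defaults to cutoff 4, two-tailed alpha 0.05.

    Returns
    -------
    RegimeShiftResult
        Year table with signed RSI, regime means/lengths and between-regime
        Welch p-values, plus the confirmed shift years.
    """
    params = params or StarsParams()
    if not isinstance(series, pd.Series):
        series = pd.Series(np.asarray(series, dtype=float))
    if series.isna().any():
        bad = list(series.index[series.isna()])
        raise ValueError(f"series contains missing values at {bad}")
    x = series.to_numpy(dtype=float)
    idx = series.index
    n = len(x)
    l = params.cutoff
    h = params.huber

    sigma = running_window_sigma(x, l)
    t_crit = stats.t.ppf(1 - params.alpha / 2, 2 * l - 2)
    diff = t_crit * np.sqrt(2.0 * sigma ** 2 / l)

    rsi = np.zeros(n)
    shift_pos: list[int] = []
    regime_start = 0
    # Scan from the second observation on: the current-regime mean is taken
    # over the regime's values so far, so a shift can be flagged even inside
    # the first l years (and, symmetrically, near the end of the series).
    i = 1
    while i < n:
        vals = x[regime_start:i]
        m_r = _weighted_regime_mean(vals, sigma, h, params.mean_passes)
        if x[i] > m_r + diff:
            sign, level = 1.0, m_r + diff
        elif x[i] < m_r - diff:
            sign, level = -1.0, m_r - diff
        else:
            i += 1
            continue
        # candidate shift at i: test up to l years from the candidate on
        # (Huber-weighted) anomalies beyond the critical level
        sw = swz = 0.0
        confirmed = sigma > 0
        for j in range(i, min(i + l, n)):
            z = (x[j] - level) * sign / sigma
            w = 1.0 if abs(z) <= h else h / abs(z)
            sw += w
            swz += w * z
            if swz < 0:
                confirmed = False
                break
        if confirmed and sw > 0:
            rsi[i] = sign * swz / sw
            shift_pos.append(i)
            regime_start = i
        i += 1

    # regime assignment and summaries (plain means, as reported)
    bounds = [0] + shift_pos + [n]
    regime_id = np.zeros(n, dtype=int)
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        regime_id[a:b] = k

    mean_col = np.empty(n)
    len_col = np.empty(n, dtype=int)
    conf_col = np.full(n, np.nan)
    for k, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        mean_col[a:b] = x[a:b].mean()
        len_col[a:b] = b - a
        if k > 0:
            prev = x[bounds[k - 1]:a]
            cur = x[a:b]
            if len(prev) > 1 and len(cur) > 1:
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    conf_col[a] = stats.ttest_ind(cur, prev,
                                                  equal_var=False).pvalue

    table = pd.DataFrame(
        {"value": x, "rsi": rsi, "mean": mean_col, "length": len_col,
         "regime": regime_id, "confidence": conf_col},
        index=idx,
    )
    return RegimeShiftResult(
        table=table, shift_years=[idx[p] for p in shift_pos],
        sigma_l=sigma, diff=diff, params=params,
    )


def stars_sweep(series: pd.Series, l_range=range(3, 11),
                alpha: float = 0.05, **kwargs) -> pd.DataFrame:
    """Robustness sweep of the scan over expected regime lengths.

    Returns a table with one row per (cutoff, shift year), plus a
    ``robustness`` table attribute: for each boundary year, the fraction of
    cutoff values at which it was detected.
    """
    rows = []
    for l in l_range:
        res = stars(series, StarsParams(cutoff=l, alpha=alpha, **kwargs))
        for y in res.shift_years:
            rows.append({"cutoff": l, "shift_year": y,
                         "rsi": res.table.loc[y, "rsi"]})
    out = pd.DataFrame(rows, columns=["cutoff", "shift_year", "rsi"])
    n_l = len(list(l_range))
    robustness = (out.groupby("shift_year").size() / n_l).rename("robustness")
    out.attrs["robustness"] = robustness
    return out
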