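"""Distribution-abundance curve fitting and information-theoretic model selection.

Candidate models for an occupancy-vs-abundance scatter:

* ``mean`` — a single horizontal line (null model);
* ``linear`` — ordinary least squares line;
* ``saturating`` — ``y = a*(1 - b**x)``, the decelerating form expected of
  occupancy as mean local density grows;
* segmented (piecewise) families with one breakpoint ``x*``: two horizontal
  lines (``seg_horizontal_horizontal``), a sloping then a horizontal segment
  (``seg_sloping_horizontal``), the reverse (``seg_horizontal_sloping``), and
  two independent sloping lines (``seg_sloping_sloping``).

Parameter counts K follow the convention that the error variance is a
parameter (mean: 2, linear: 3, saturating: 3, horizontal/horizontal: 4,
sloping/horizontal: 5, sloping/sloping: 6).  Many packages count K without
the variance; the AICc ranking here assumes the convention above.

Model ranking uses AIC = n*ln(RSS/n) + 2K and the small-sample correction
AICc = AIC + 2K(K+1)/(n-K-1), with Akaike weights and evidence ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CandidateModel", "Breakpoint", "ContrastSet",
    "fit_mean", "fit_linear", "fit_saturating", "fit_segmented",
    "aicc_rank", "pic_regression", "cooks_outliers",
    "SEGMENTED_FAMILIES", "K_BY_FAMILY",
]

SEGMENTED_FAMILIES = (
    "seg_horizontal_horizontal", "seg_sloping_horizontal",
    "seg_horizontal_sloping", "seg_sloping_sloping",
)

#: parameter count per family, error variance included
K_BY_FAMILY = {
    "mean": 2, "linear": 3, "saturating": 3,
    "seg_horizontal_horizontal": 4, "seg_sloping_horizontal": 5,
    "seg_horizontal_sloping": 5, "seg_sloping_sloping": 6,
}


@dataclass
class Breakpoint:
    x_star: float
    ci: tuple = (np.nan, np.nan)
    f_stat: float = np.nan
    p_value: float = np.nan


@dataclass
class CandidateModel:
    family: str
    params: dict
    K: int
    rss: float
    n: int
    r2: float = np.nan
    breakpoint: Breakpoint | None = None
    flags: list = field(default_factory=list)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "mean":
            return np.full_like(x, p["mean"])
        if self.family == "linear":
            return p["intercept"] + p["slope"] * x
        if self.family == "saturating":
            return p["a"] * (1.0 - p["b"] ** x)
        if self.family in SEGMENTED_FAMILIES:
            left = x <= p["x_star"]
            out = np.empty_like(x)
            out[left] = p["left_intercept"] + p["left_slope"] * x[left]
            out[~left] = p["right_intercept"] + p["right_slope"] * x[~left]
            return out
        raise ValueError(f"unknown family {self.family!r}")


def _as_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def _r2(y, rss):
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else np.nan


def fit_mean(x, y) -> CandidateModel:
    x, y = _as_xy(x, y)
    m = float(y.mean())
    rss = float(np.sum((y - m) ** 2))
    return CandidateModel("mean", {"mean": m}, 2, rss, len(y), _r2(y, rss))


def fit_linear(x, y) -> CandidateModel:
    x, y = _as_xy(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (intercept + slope * x)) ** 2))
    return CandidateModel(
        "linear", {"intercept": float(intercept), "slope": float(slope)},
        3, rss, len(y), _r2(y, rss),
    )


def fit_saturating(x, y, *, a0: float | None = None, b0: float = 0.5) -> CandidateModel:
    """Least-squares fit of the saturating form ``y = a*(1 - b**x)``.

    ``a`` is the asymptotic occupancy, ``b in (0, 1)`` controls how fast the
    curve saturates.  Initialised at ``a0 = max(y)``, ``b0 = 0.5``; bounded
    ``a in (0, 2*max(y)]``, ``b in (1e-6, 1 - 1e-6)``.
    """
    x, y = _as_xy(x, y)
    if len(x) < 4:
        raise ValueError("saturating fit needs n >= 4")
    if (x < 0).any():
        raise ValueError("saturating fit requires x >= 0")
    flags = []
    ymax = float(y.max())
    if ymax <= 0 or np.allclose(y, y[0]):
        flags.append("degenerate")
        ymax = max(ymax, 1.0)
    a0 = ymax if a0 is None else a0

    def f(x, a, b):
        return a * (1.0 - b ** x)

    try:
        popt, pcov = optimize.curve_fit(
            f, x, y, p0=(a0, b0),
            bounds=((1e-9, 1e-6), (2 * max(ymax, 1e-9), 1 - 1e-6)),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"saturating fit did not converge: {err}") from err
    a, b = map(float, popt)
    se = np.sqrt(np.diag(pcov)) if np.isfinite(pcov).all() else [np.nan, np.nan]
    rss = float(np.sum((y - f(x, a, b)) ** 2))
    if b < 1e-5 or b > 1 - 1e-5:
        flags.append("b_at_bound")
    return CandidateModel(
        "saturating",
        {"a": a, "b": b, "a_se": float(se[0]), "b_se": float(se[1])},
        3, rss, len(y), _r2(y, rss), flags=flags,
    )


def _segment_fit(x, y, sloping: bool):
    """(intercept, slope, rss) for one segment; horizontal = segment mean."""
    if sloping:
        if len(np.unique(x)) < 2:
            m = float(y.mean())
            return m, 0.0, float(np.sum((y - m) ** 2))
        slope, intercept = np.polyfit(x, y, 1)
        rss = float(np.sum((y - (intercept + slope * x)) ** 2))
        return float(intercept), float(slope), rss
    m = float(y.mean())
    return m, 0.0, float(np.sum((y - m) ** 2))


def _segmented_rss(x, y, family, min_seg):
    """Grid search over breakpoint candidates; returns best fit tuple."""
    left_sloping = family in ("seg_sloping_horizontal", "seg_sloping_sloping")
    right_sloping = family in ("seg_horizontal_sloping", "seg_sloping_sloping")
    xs = np.unique(x)
    candidates = (xs[:-1] + xs[1:]) / 2.0
    best = None
    for bp in candidates:
        lmask = x <= bp
        if lmask.sum() < min_seg or (~lmask).sum() < min_seg:
            continue
        li, ls, lrss = _segment_fit(x[lmask], y[lmask], left_sloping)
        ri, rs, rrss = _segment_fit(x[~lmask], y[~lmask], right_sloping)
        rss = lrss + rrss
        # ties broken toward the smaller breakpoint (strict < keeps first)
        if best is None or rss < best[0] - 1e-12:
            # the breakpoint is only identified up to the gap between the
            # flanking x values; keep that equivalence interval
            best = (rss, bp, li, ls, ri, rs,
                    float(x[lmask].max()), float(x[~lmask].min()))
    return best


def fit_segmented(x, y, family: str = "seg_horizontal_horizontal", *,
                  min_seg: int = 3, n_boot: int = 999,
                  seed: int | None = None, ci_level: float = 0.95) -> CandidateModel:
    """Piecewise fit with a single breakpoint chosen by minimum total RSS.

    Breakpoint candidates are midpoints of consecutive distinct sorted x;
    each segment is fit by least squares (a horizontal segment is its mean).
    Significance against the nested non-segmented alternative (mean for
    horizontal/horizontal, linear otherwise) is an F-test with degrees of
    freedom corrected for the added parameters (the breakpoint counts as
    one).  The breakpoint confidence interval is a case-resampling bootstrap
    percentile interval.
    """
    x, y = _as_xy(x, y)
    if family not in SEGMENTED_FAMILIES:
        raise ValueError(f"unknown segmented family {family!r}")
    n = len(x)
    if n < 2 * min_seg:
        raise ValueError(f"need at least {2*min_seg} points for {family}")
    best = _segmented_rss(x, y, family, min_seg)
    if best is None:
        raise ValueError("too few distinct x values for the requested segments")
    rss, bp, li, ls, ri, rs, _, _ = best

    # F-test vs the nested single-segment model
    null = fit_mean(x, y) if family == "seg_horizontal_horizontal" else fit_linear(x, y)
    p_full = K_BY_FAMILY[family] - 1          # regression params incl. breakpoint
    p_null = null.K - 1
    df1 = p_full - p_null
    df2 = n - p_full
    if df2 > 0 and rss > 0:
        f_stat = ((null.rss - rss) / df1) / (rss / df2)
        p_value = float(stats.f.sf(f_stat, df1, df2))
    elif rss == 0 and null.rss > 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat, p_value = np.nan, np.nan

    # Bootstrap CI: a breakpoint is only identified up to the interval
    # between the flanking x values (every cut inside the gap gives the
    # same RSS), so the CI is built from the percentile spread of the
    # resampled equivalence-interval endpoints rather than of the
    # (arbitrary) gap midpoints, which would badly under-cover.
    ci = (np.nan, np.nan)
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        lo_ends, hi_ends = [], []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            b = _segmented_rss(x[idx], y[idx], family, min_seg)
            if b is not None:
                lo_ends.append(b[6])
                hi_ends.append(b[7])
        if lo_ends:
            tail = (1 - ci_level) / 2 * 100
            ci = (float(np.percentile(lo_ends, tail)),
                  float(np.percentile(hi_ends, 100 - tail)))

    params = {"left_intercept": li, "left_slope": ls,
              "right_intercept": ri, "right_slope": rs, "x_star": float(bp)}
    return CandidateModel(
        family, params, K_BY_FAMILY[family], float(rss), n, _r2(y, rss),
        breakpoint=Breakpoint(float(bp), ci, float(f_stat), p_value),
    )


def fit_all(x, y, families=None, *, min_seg: int = 3, n_boot: int = 0,
            seed: int | None = None) -> list[CandidateModel]:
    """Fit the standard candidate set on one (x, y) scatter."""
    x, y = _as_xy(x, y)
    if families is None:
        families = ["mean", "linear", "saturating",
                    "seg_horizontal_horizontal", "seg_sloping_horizontal",
                    "seg_sloping_sloping"]
    out = []
    for fam in families:
        try:
            if fam == "mean":
                out.append(fit_mean(x, y))
            elif fam == "linear":
                out.append(fit_linear(x, y))
            elif fam == "saturating":
                out.append(fit_saturating(x, y))
            else:
                out.append(fit_segmented(x, y, fam, min_seg=min_seg,
                                         n_boot=n_boot, seed=seed))
        except (ValueError, RuntimeError):
            continue
    return out


def aicc_rank(models: list[CandidateModel] | pd.DataFrame) -> pd.DataFrame:
    """Rank candidate models by AICc with Akaike weights and evidence ratios.

    Accepts fitted :class:`CandidateModel` objects or a frame with columns
    ``family``, ``K``, ``n``, ``rss`` (e.g. a published model table).
    Models with undefined AICc (n <= K+1) are flagged and excluded from the
    weight normalization.
    """
    if isinstance(models, pd.DataFrame):
        rows = models[["family", "K", "n", "rss"]].to_dict("records")
    else:
        rows = [{"family": m.family, "K": m.K, "n": m.n, "rss": m.rss}
                for m in models]
    if not rows:
        raise ValueError("no models to rank")
    tab = pd.DataFrame(rows)
    if tab["n"].nunique() != 1:
        raise ValueError("all models must be fit to the same data (equal n)")
    n = int(tab["n"].iloc[0])
    with np.errstate(divide="ignore"):
        tab["aic"] = n * np.log(tab["rss"] / n) + 2 * tab["K"]
    denom = n - tab["K"] - 1
    tab["aicc"] = np.where(denom > 0, tab["aic"] + 2 * tab["K"] * (tab["K"] + 1)
                           / denom.replace(0, np.nan), np.nan)
    tab["aicc_defined"] = denom > 0
    best = tab.loc[tab["aicc_defined"], "aicc"].min()
    tab["delta"] = tab["aicc"] - best
    tab["rel_lik"] = np.exp(-tab["delta"] / 2)
    wsum = tab.loc[tab["aicc_defined"], "rel_lik"].sum()
    tab["weight"] = np.where(tab["aicc_defined"], tab["rel_lik"] / wsum, np.nan)
    tab["evidence_ratio"] = tab["weight"].max() / tab["weight"]
    tab["best"] = tab["delta"] == 0
    return tab.sort_values("aicc").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts


@dataclass
class ContrastSet:
    contrasts: pd.DataFrame         # one row per internal node: x, y contrast
    slope: float
    slope_se: float
    t: float
    p_value: float
    n_contrasts: int
    flags: list = field(default_factory=list)


def _pic_postorder(tree, trait: dict) -> list[tuple[str, float, float]]:
    """Felsenstein contrasts by post-order node averaging.

    Returns (node label, standardized contrast, branch variance) per
    internal node; annotates working values/extended lengths on the fly.
    """
    contrasts = []
    values, lengths = {}, {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        values[leaf] = float(trait[name])
        lengths[leaf] = leaf.edge.length
    for node in tree.postorder_internal_node_iter():
        ch = node.child_nodes()
        if len(ch) != 2:
            raise ValueError("tree must be fully bifurcating for contrasts")
        c1, c2 = ch
        v1, v2 = lengths[c1], lengths[c2]
        contrast = (values[c1] - values[c2]) / np.sqrt(v1 + v2)
        contrasts.append((node, contrast, v1 + v2))
        values[node] = (values[c1] / v1 + values[c2] / v2) / (1 / v1 + 1 / v2)
        ext = v1 * v2 / (v1 + v2)
        lengths[node] = (node.edge.length or 0.0) + ext
    return contrasts


def pic_regression(tree, trait_x: dict, trait_y: dict, *,
                   unit_lengths: bool = False) -> ContrastSet:
    """Regression through the origin of y-contrasts on x-contrasts.

    ``tree`` is a dendropy Tree whose tip labels match the keys of the two
    trait dicts.  Contrasts are Felsenstein's standardized differences with
    branch-length extension ``v' = v + v1*v2/(v1+v2)``.  With
    ``unit_lengths=True`` every branch is set to length 1 first (the usual
    fallback for a cladogram without estimated lengths).
    """
    tree = tree.clone(depth=1)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips.symmetric_difference(trait_x) | tips.symmetric_difference(trait_y)
    if missing:
        raise ValueError(f"tip/trait mismatch for: {sorted(missing)}")
    if unit_lengths:
        for edge in tree.preorder_edge_iter():
            edge.length = 1.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not (node.edge.length or 0) > 0:
            raise ValueError(
                "non-positive branch length; pass unit_lengths=True to use "
                "a unit-length cladogram")

    cx = _pic_postorder(tree, trait_x)
    cy = _pic_postorder(tree, trait_y)
    u = np.array([c for _, c, _ in cx])
    v = np.array([c for _, c, _ in cy])
    # positivize on x (contrast sign is arbitrary per node)
    sign = np.where(u < 0, -1.0, 1.0)
    u, v = u * sign, v * sign
    df = pd.DataFrame({"contrast_x": u, "contrast_y": v})
    flags = []
    ssx = float(np.sum(u ** 2))
    if ssx == 0:
        flags.append("all_contrasts_zero")
        return ContrastSet(df, np.nan, np.nan, np.nan, np.nan, len(u), flags)
    slope = float(np.sum(u * v) / ssx)
    resid = v - slope * u
    dof = len(u) - 1
    se = float(np.sqrt(np.sum(resid ** 2) / dof / ssx)) if dof > 0 else np.nan
    t = slope / se if se and se > 0 else np.nan
    p = 2 * float(stats.t.sf(abs(t), dof)) if np.isfinite(t) else np.nan
    return ContrastSet(df, slope, se, t, p, len(u), flags)


def cooks_outliers(x, y, *, cutoff: float | None = None):
    """Cook's distance per point for a linear fit; flag D > 4/n.

    Returns (distances, flagged indices, cutoff).
    """
    import statsmodels.api as sm

    x, y = _as_xy(x, y)
    n = len(x)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if model.ssr <= 1e-12 * max(tss, 1.0):
        # exact fit: distances are 0/0 float noise
        d = np.zeros(n)
    else:
        d = model.get_influence().cooks_distance[0]
    cut = 4.0 / n if cutoff is None else cutoff
    flagged = np.nonzero(d > cut)[0]
    return d, flagged, cut
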