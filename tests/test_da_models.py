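"""Curve fitting and AICc model selection: exact recoveries, brute-force
oracles, the published model-selection table, and contrast regression."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from pondshift.da_models import (K_BY_FAMILY, aicc_rank, cooks_outliers,
                                 fit_all, fit_linear, fit_mean,
                                 fit_saturating, fit_segmented,
                                 pic_regression)
from pondshift.refdata import CONSTRAINED_DA_MODEL_TABLE


class TestSaturating:
    def test_noiseless_recovery(self):
        x = np.arange(1, 7, dtype=float)
        m = fit_saturating(x, 2 * (1 - 0.5 ** x))
        assert m.params["a"] == pytest.approx(2.0, abs=1e-6)
        assert m.params["b"] == pytest.approx(0.5, abs=1e-6)
        assert m.rss == pytest.approx(0.0, abs=1e-12)
        assert m.K == 3

    def test_constant_y_is_flagged_degenerate(self):
        x = np.arange(1, 8, dtype=float)
        m = fit_saturating(x, np.full(7, 0.4))
        assert "degenerate" in m.flags or "b_at_bound" in m.flags

    def test_noisy_parameter_recovery_within_3se(self, rng):
        a, b, n = 1.0, 0.3, 13
        x = np.linspace(0.2, 8, n)
        y = a * (1 - b ** x) + rng.normal(0, 0.05, n)
        m = fit_saturating(x, y)
        assert abs(m.params["a"] - a) < 3 * m.params["a_se"]
        assert abs(m.params["b"] - b) < 3 * max(m.params["b_se"], 1e-6)

    def test_prediction_monotone_and_bounded(self):
        x = np.arange(1, 7, dtype=float)
        m = fit_saturating(x, 2 * (1 - 0.5 ** x))
        grid = np.linspace(0, 20, 100)
        pred = m.predict(grid)
        assert (np.diff(pred) >= -1e-12).all()
        assert (pred <= m.params["a"] + 1e-9).all()

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_saturating([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_saturating([-1, 2, 3, 4], [1, 2, 3, 4])


class TestSegmented:
    def test_noiseless_step_recovered_exactly(self):
        x = np.array([1, 2, 3, 4, 6, 7, 8, 9], float)
        y = (x > 5).astype(float)
        m = fit_segmented(x, y, "seg_horizontal_horizontal", n_boot=0)
        assert 4 < m.params["x_star"] < 6
        assert m.rss == pytest.approx(0.0, abs=1e-12)
        assert m.breakpoint.p_value == pytest.approx(0.0, abs=1e-12)

    def test_pure_linear_gains_no_significant_break(self, rng):
        x = np.linspace(0, 10, 16)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 16)
        m = fit_segmented(x, y, "seg_sloping_sloping", n_boot=0)
        assert m.breakpoint.p_value > 0.05

    @pytest.mark.parametrize("family", ["seg_horizontal_horizontal",
                                        "seg_sloping_horizontal",
                                        "seg_sloping_sloping"])
    def test_grid_search_matches_brute_force_oracle(self, rng, family):
        """Independent enumeration over every contiguous split of the
        sorted points must find the same minimum RSS."""
        n = 18
        x = np.sort(rng.uniform(0, 10, n))
        y = np.where(x < 4, 1.0, 3.0) + 0.3 * x * (family != "seg_horizontal_horizontal") \
            + rng.normal(0, 0.4, n)
        m = fit_segmented(x, y, family, min_seg=3, n_boot=0)

        def seg_rss(xx, yy, sloping):
            if sloping:
                coef = np.polyfit(xx, yy, 1)
                return float(np.sum((yy - np.polyval(coef, xx)) ** 2))
            return float(np.sum((yy - yy.mean()) ** 2))

        ls = family in ("seg_sloping_horizontal", "seg_sloping_sloping")
        rs = family == "seg_sloping_sloping"
        best = np.inf
        for k in range(3, n - 2):
            rss = seg_rss(x[:k], y[:k], ls) + seg_rss(x[k:], y[k:], rs)
            best = min(best, rss)
        assert m.rss == pytest.approx(best, rel=1e-9)

    def test_segmented_never_fits_worse_than_nested_model(self, rng):
        x = np.sort(rng.uniform(0, 10, 14))
        y = rng.normal(2, 1, 14)
        hh = fit_segmented(x, y, "seg_horizontal_horizontal", n_boot=0)
        assert hh.rss <= fit_mean(x, y).rss + 1e-12
        ss = fit_segmented(x, y, "seg_sloping_sloping", n_boot=0)
        assert ss.rss <= fit_linear(x, y).rss + 1e-12

    def test_bootstrap_ci_brackets_true_break_on_clean_step(self, rng):
        x = np.sort(rng.uniform(0, 10, 20))
        y = np.where(x < 5, 1.0, 4.0) + rng.normal(0, 0.3, 20)
        m = fit_segmented(x, y, "seg_horizontal_horizontal",
                          n_boot=199, seed=7)
        lo, hi = m.breakpoint.ci
        assert lo <= 5 <= hi

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            fit_segmented([1, 2, 3], [1, 2, 3], "seg_horizontal_horizontal")


class TestAiccRank:
    def test_reference_model_table_arithmetic(self):
        """Feeding the published per-model (RSS, K, n) reproduces the
        printed Akaike weights/evidence ratios.  RSS is printed to 2
        decimals, which propagates to ~0.4 on AICc/delta for some rows,
        and ~0.01 on weights."""
        tab = aicc_rank(CONSTRAINED_DA_MODEL_TABLE).set_index("family")
        sat = tab.loc["saturating"]
        hh = tab.loc["seg_horizontal_horizontal"]
        assert bool(sat["best"])
        assert sat["aicc"] - sat["aic"] == pytest.approx(2.667, abs=1e-2)
        assert sat["weight"] == pytest.approx(0.692, abs=0.02)
        assert hh["weight"] == pytest.approx(0.292, abs=0.02)
        assert hh["evidence_ratio"] == pytest.approx(2.37, abs=0.15)
        printed = {"saturating": (-48.40, 0.00),
                   "seg_horizontal_horizontal": (-46.67, 1.73),
                   "linear": (-39.70, 8.70),
                   "seg_sloping_horizontal": (-39.09, 9.30),
                   "mean": (-35.27, 13.13),
                   "seg_sloping_sloping": (-31.25, 17.15)}
        for fam, (aicc, delta) in printed.items():
            assert tab.loc[fam, "aicc"] == pytest.approx(aicc, abs=0.45), fam
            assert tab.loc[fam, "delta"] == pytest.approx(delta, abs=0.45), fam

    def test_weights_sum_to_one_and_best_ratio_is_one(self):
        tab = aicc_rank(CONSTRAINED_DA_MODEL_TABLE)
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert tab["evidence_ratio"].min() == pytest.approx(1.0)
        assert (tab["evidence_ratio"] >= 1 - 1e-12).all()

    def test_single_model_and_symmetry(self):
        single = aicc_rank(pd.DataFrame(
            [{"family": "mean", "K": 2, "n": 10, "rss": 1.0}]))
        assert single.loc[0, "delta"] == 0
        assert single.loc[0, "weight"] == pytest.approx(1.0)
        pair = aicc_rank(pd.DataFrame([
            {"family": "a", "K": 3, "n": 10, "rss": 1.0},
            {"family": "b", "K": 3, "n": 10, "rss": 1.0}]))
        assert pair["weight"].to_numpy() == pytest.approx([0.5, 0.5])

    def test_undefined_aicc_flagged_when_n_too_small(self):
        tab = aicc_rank(pd.DataFrame([
            {"family": "mean", "K": 2, "n": 8, "rss": 1.0},
            {"family": "big", "K": 7, "n": 8, "rss": 0.5}]))
        row = tab.set_index("family").loc["big"]
        assert not row["aicc_defined"]
        assert np.isnan(row["weight"])

    def test_k_convention_includes_error_variance(self):
        assert K_BY_FAMILY["mean"] == 2
        assert K_BY_FAMILY["seg_sloping_sloping"] == 6
        x = np.arange(8, dtype=float)
        assert fit_mean(x, x).K == 2
        assert fit_linear(x, x).K == 3


def _gls_slope_oracle(tree, tx, ty):
    """Independent check: under Brownian motion the PIC regression-through-
    origin slope equals the GLS slope with the phylogenetic covariance."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(tx)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            C[i, j] = depth - pdm.patristic_distance(taxa[a], taxa[b]) / 2.0
    Vi = np.linalg.inv(C)
    one = np.ones(n)
    xv = np.array([tx[l] for l in labels])
    yv = np.array([ty[l] for l in labels])
    # GLS slope with phylogenetically-estimated means removed
    ax = (one @ Vi @ xv) / (one @ Vi @ one)
    ay = (one @ Vi @ yv) / (one @ Vi @ one)
    xc, yc = xv - ax, yv - ay
    return float((xc @ Vi @ yc) / (xc @ Vi @ xc))


class TestPic:
    def test_two_taxon_closed_form(self):
        t = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        cs = pic_regression(t, {"A": 3.0, "B": 1.0}, {"A": 5.0, "B": 1.0})
        assert cs.n_contrasts == 1
        assert abs(cs.contrasts["contrast_x"][0]) == pytest.approx(2 / np.sqrt(2))
        assert cs.slope == pytest.approx(2.0)

    @pytest.mark.parametrize("newick", [
        "((A:1,B:1):1,(C:1,D:1):1);",
        "(((A:2,B:1):1,C:3):1,(D:1,E:2):2);",
        "((((A:1,B:1):1,C:2):1,D:3):1,((E:1,F:1):1,(G:1,H:1):1):2);",
    ])
    def test_slope_matches_gls_oracle(self, newick, rng):
        t = dendropy.Tree.get(data=newick, schema="newick")
        labels = [leaf.taxon.label for leaf in t.leaf_node_iter()]
        tx = {l: float(v) for l, v in zip(labels, rng.normal(0, 1, len(labels)))}
        ty = {l: 2 * tx[l] + float(e)
              for l, e in zip(labels, rng.normal(0, 0.5, len(labels)))}
        cs = pic_regression(t, tx, ty)
        assert cs.n_contrasts == len(labels) - 1
        assert cs.slope == pytest.approx(_gls_slope_oracle(t, tx, ty), abs=1e-8)

    def test_identical_traits_flagged(self):
        t = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                              schema="newick")
        flat = {k: 1.0 for k in "ABCD"}
        cs = pic_regression(t, flat, flat)
        assert "all_contrasts_zero" in cs.flags
        assert np.isnan(cs.slope)

    def test_zero_branch_lengths_suggest_unit_substitution(self):
        t = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        traits = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        with pytest.raises(ValueError, match="unit_lengths"):
            pic_regression(t, traits, traits)
        cs = pic_regression(t, traits, traits, unit_lengths=True)
        assert cs.n_contrasts == 3

    def test_tip_mismatch_error(self):
        t = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        with pytest.raises(ValueError, match="mismatch"):
            pic_regression(t, {"A": 1.0, "C": 2.0}, {"A": 1.0, "C": 2.0})


class TestCooksOutliers:
    def test_cutoff_is_4_over_n(self):
        x = np.linspace(0, 10, 14)
        _, _, cut = cooks_outliers(x, 2 * x)
        assert cut == pytest.approx(4 / 14)

    def test_gross_outlier_flagged(self):
        x = np.linspace(0, 10, 14)
        y = 2 * x + 1
        y[7] += 30
        _, flagged, _ = cooks_outliers(x, y)
        assert list(flagged) == [7]

    def test_perfect_line_has_no_flags(self):
        x = np.linspace(0, 10, 10)
        _, flagged, _ = cooks_outliers(x, 3 * x - 1)
        assert len(flagged) == 0


def test_fit_all_returns_ranked_table_ready_models(rng):
    x = np.sort(rng.uniform(0, 8, 14))
    y = 3 * (1 - 0.4 ** x) + rng.normal(0, 0.2, 14)
    models = fit_all(x, y)
    tab = aicc_rank(models)
    assert set(tab["family"]) >= {"mean", "linear", "saturating"}
    assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
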