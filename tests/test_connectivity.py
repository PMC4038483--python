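"""Incidence-function index and circuit-theory resistance."""

import numpy as np
import pandas as pd
import pytest

from pondshift.connectivity import (ResistanceMatrix, compare_occupied,
                                    effective_resistance, hanski_index,
                                    region_resistance_summary)
from pondshift.core_io import FrictionRaster


def _ponds(coords):
    return pd.DataFrame(
        [{"x": x, "y": y} for x, y in coords],
        index=pd.Index([f"p{i}" for i in range(len(coords))],
                       name="pond_id"))


class TestHanski:
    def test_single_pond_is_zero(self):
        idx = hanski_index(_ponds([(0, 0)]), pd.Series({"p0": 50.0}))
        assert idx["p0"] == 0.0

    def test_two_pond_closed_form(self):
        ponds = _ponds([(0, 0), (125, 0)])
        idx = hanski_index(ponds, pd.Series({"p0": 0.0, "p1": 100.0}),
                           alpha=1 / 125)
        assert idx["p0"] == pytest.approx(100 * np.exp(-1))

    def test_five_ponds_match_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 500, (5, 2))
        ponds = _ponds([tuple(c) for c in coords])
        pops = pd.Series(rng.uniform(0, 100, 5), index=ponds.index)
        alpha = 1 / 125
        got = hanski_index(ponds, pops, alpha)
        for i, pi in enumerate(ponds.index):
            s = 0.0
            for j, pj in enumerate(ponds.index):
                if i == j:
                    continue
                d = np.hypot(*(coords[i] - coords[j]))
                s += pops[pj] * np.exp(-alpha * d)
            assert got[pi] == pytest.approx(s)

    def test_invariant_to_adding_empty_pond(self, rng):
        ponds = _ponds([(0, 0), (100, 0), (0, 100)])
        pops = pd.Series([10.0, 20.0, 30.0], index=ponds.index)
        base = hanski_index(ponds, pops)
        bigger = _ponds([(0, 0), (100, 0), (0, 100), (50, 50)])
        pops2 = pd.Series([10.0, 20.0, 30.0, 0.0], index=bigger.index)
        grown = hanski_index(bigger, pops2)
        np.testing.assert_allclose(grown[:3], base)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            hanski_index(_ponds([(0, 0), (1, 1)]),
                         pd.Series({"p0": -1.0, "p1": 2.0}))


def _uniform_raster(shape, friction=1.0, cellsize=1.0):
    return FrictionRaster(values=np.full(shape, friction), cellsize=cellsize)


class TestResistance:
    def test_single_edge_is_ohms_law(self):
        # two cells of friction f: conductance 2/(f+f) = 1/f, R = f
        r = effective_resistance(_uniform_raster((1, 2), friction=3.0),
                                 {"a": (0, 0), "b": (0, 1)})
        assert r.resistance.loc["a", "b"] == pytest.approx(3.0)

    def test_series_resistances_add(self):
        r = effective_resistance(_uniform_raster((1, 4), friction=2.0),
                                 {"a": (0, 0), "b": (0, 3)})
        assert r.resistance.loc["a", "b"] == pytest.approx(3 * 2.0)

    def test_grid_matches_laplacian_pseudoinverse_oracle(self):
        fr = _uniform_raster((3, 3))
        r = effective_resistance(fr, {"a": (0, 0), "b": (2, 2)})
        # oracle: dense Laplacian pseudoinverse on the same lattice
        n = 9
        L = np.zeros((n, n))
        for i in range(3):
            for j in range(3):
                u = 3 * i + j
                for di, dj in ((0, 1), (1, 0)):
                    if i + di < 3 and j + dj < 3:
                        v = 3 * (i + di) + (j + dj)
                        L[u, u] += 1
                        L[v, v] += 1
                        L[u, v] -= 1
                        L[v, u] -= 1
        Li = np.linalg.pinv(L, hermitian=True)
        expect = Li[0, 0] + Li[8, 8] - 2 * Li[0, 8]
        assert r.resistance.loc["a", "b"] == pytest.approx(expect)

    def test_symmetry_and_triangle_inequality(self, rng):
        fr = FrictionRaster(values=rng.uniform(1, 10, (6, 6)), cellsize=1.0)
        cells = {"a": (0, 0), "b": (5, 5), "c": (0, 5), "d": (3, 2)}
        res = effective_resistance(fr, cells).resistance
        np.testing.assert_allclose(res, res.T)
        ids = list(cells)
        for i in ids:
            for j in ids:
                for k in ids:
                    assert res.loc[i, j] <= res.loc[i, k] + res.loc[k, j] + 1e-9

    def test_parallel_path_never_increases_resistance(self):
        # blocking the second row forces a single path; opening it adds a
        # parallel route (Rayleigh monotonicity)
        blocked = np.ones((2, 4))
        blocked[1, :] = 1000.0
        open_ = np.ones((2, 4))
        r_single = effective_resistance(
            FrictionRaster(values=blocked, cellsize=1.0),
            {"a": (0, 0), "b": (0, 3)}).resistance.loc["a", "b"]
        r_parallel = effective_resistance(
            FrictionRaster(values=open_, cellsize=1.0),
            {"a": (0, 0), "b": (0, 3)}).resistance.loc["a", "b"]
        assert r_parallel < r_single

    def test_pond_on_nodata_cell_errors(self):
        vals = np.ones((3, 3))
        vals[1, 1] = -9999.0
        fr = FrictionRaster(values=vals, cellsize=1.0)
        with pytest.raises(ValueError, match="nodata"):
            effective_resistance(fr, {"a": (1, 1)})


class TestGroupComparison:
    def test_identical_groups_give_t_zero(self):
        conn = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                         index=list("abcdef"))
        occ = pd.Series([True, True, True, False, False, False],
                        index=list("abcdef"))
        res = compare_occupied(conn, occ)
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)
        assert res["df"] == 4

    def test_two_per_group_matches_textbook_formula(self):
        conn = pd.Series([4.0, 6.0, 1.0, 3.0], index=list("abcd"))
        occ = pd.Series([True, True, False, False], index=list("abcd"))
        res = compare_occupied(conn, occ)
        sp2 = ((6 - 5) ** 2 + (4 - 5) ** 2 + (1 - 2) ** 2 + (3 - 2) ** 2) / 2
        t_hand = (5 - 2) / np.sqrt(sp2 * (1 / 2 + 1 / 2))
        assert res["t"] == pytest.approx(t_hand)
        assert res["means_ratio"] == pytest.approx(2.5)

    def test_tiny_group_returns_missing_with_warning(self):
        conn = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        occ = pd.Series([True, False, False], index=list("abc"))
        res = compare_occupied(conn, occ)
        assert np.isnan(res["t"])
        assert "warning" in res

    def test_seeded_high_index_occupancy_is_detected(self):
        """A rare species planted at the best-connected ponds should test
        significantly more connected in >=90% of replicates."""
        hits = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            coords = rng.uniform(0, 800, (30, 2))
            ponds = _ponds([tuple(c) for c in coords])
            pops = pd.Series(rng.uniform(50, 500, 30), index=ponds.index)
            idx = hanski_index(ponds, pops)
            order = idx.sort_values(ascending=False).index
            occupied = pd.Series(False, index=ponds.index)
            # occupy 10 ponds drawn preferentially from the top of the list
            take = list(order[:7]) + list(rng.choice(order[7:], 3,
                                                     replace=False))
            occupied[take] = True
            res = compare_occupied(idx, occupied)
            hits += (res["t"] > 0) and (res["p"] < 0.05)
        assert hits >= 0.9 * n_rep


class TestRegionSummary:
    def _matrix(self, values, ids):
        return ResistanceMatrix(pd.DataFrame(values, index=ids, columns=ids),
                                {})

    def test_single_region_equals_global(self):
        ids = list("abc")
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        m = self._matrix(vals, ids)
        tab = region_resistance_summary(
            m, pd.Series(["west"] * 3, index=ids)).set_index("region")
        assert tab.loc["west", "mean"] == tab.loc["global", "mean"]

    def test_corridor_raises_global_mean(self):
        # two tight clusters joined through a high-resistance corridor
        ids = list("abcd")
        vals = np.array([[0, 1, 10, 10], [1, 0, 10, 10],
                         [10, 10, 0, 1], [10, 10, 1, 0]], float)
        m = self._matrix(vals, ids)
        regions = pd.Series(["w", "w", "e", "e"], index=ids)
        tab = region_resistance_summary(m, regions).set_index("region")
        assert tab.loc["global", "mean"] > tab.loc["w", "mean"]
        assert tab.loc["global", "mean"] > tab.loc["e", "mean"]

    def test_invariant_to_pond_order(self):
        ids = list("abcd")
        vals = np.array([[0, 1, 4, 5], [1, 0, 6, 7],
                         [4, 6, 0, 2], [5, 7, 2, 0]], float)
        regions = pd.Series(["w", "w", "e", "e"], index=ids)
        t1 = region_resistance_summary(self._matrix(vals, ids), regions)
        perm = [2, 0, 3, 1]
        ids2 = [ids[i] for i in perm]
        vals2 = vals[np.ix_(perm, perm)]
        t2 = region_resistance_summary(self._matrix(vals2, ids2),
                                       regions.reindex(ids2))
        pd.testing.assert_frame_equal(
            t1.sort_values("region").reset_index(drop=True),
            t2.sort_values("region").reset_index(drop=True))

    def test_tiny_region_flagged(self):
        ids = list("abc")
        vals = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float)
        regions = pd.Series(["w", "w", "e"], index=ids)
        tab = region_resistance_summary(self._matrix(vals, ids),
                                        regions).set_index("region")
        assert tab.loc["e", "flag"] == "too_few"
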