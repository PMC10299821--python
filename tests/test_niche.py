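import numpy as np
import pandas as pd
import pytest

from mungpop.niche import (
    ClimateRaster,
    SuitabilitySurface,
    climate_pca_manova,
    decorrelate_variables,
    extract_climate,
    read_ascii_grid,
    schoeners_d,
    suitability_surface,
    wilks_lambda,
)


def _raster(values, name="x", xll=0.0, yll=0.0, cell=1.0, nodata=-9999.0):
    return ClimateRaster(name=name, values=np.asarray(values, float),
                         xll=xll, yll=yll, cellsize=cell, nodata=nodata)


class TestRasterIO:
    def test_ascii_round_trip(self, tmp_path):
        ras = _raster([[1.5, 2.25], [3.0, -9999.0]])
        path = tmp_path / "x.asc"
        ras.write_ascii(str(path))
        back = read_ascii_grid(str(path), name="x")
        np.testing.assert_array_equal(back.values, ras.values)
        assert (back.xll, back.yll, back.cellsize) == (0.0, 0.0, 1.0)

    def test_cell_lookup_orientation(self):
        # row 0 is the northernmost row
        ras = _raster([[1.0, 2.0], [3.0, 4.0]])
        assert ras.value_at(0.5, 1.5) == 1.0  # NW
        assert ras.value_at(1.5, 0.5) == 4.0  # SE

    def test_outside_extent_raises(self):
        ras = _raster([[1.0]])
        with pytest.raises(ValueError):
            ras.value_at(5.0, 0.5)


class TestExtract:
    def test_corner_points_order_preserving(self):
        ras = _raster([[10.0, 20.0], [30.0, 40.0]])
        occ = pd.DataFrame({
            "id": list("abcd"), "group": ["g"] * 4,
            "lon": [0.5, 1.5, 0.5, 1.5], "lat": [1.5, 1.5, 0.5, 0.5],
        })
        out = extract_climate(occ, {"x": ras})
        assert out["x"].tolist() == [10.0, 20.0, 30.0, 40.0]

    def test_nodata_flagged(self):
        ras = _raster([[10.0, -9999.0]])
        occ = pd.DataFrame({"id": ["a", "b"], "group": ["g", "g"],
                            "lon": [0.5, 1.5], "lat": [0.5, 0.5]})
        out = extract_climate(occ, {"x": ras})
        assert out["valid"].tolist() == [True, False]


class TestDecorrelate:
    def test_duplicate_variable_keeps_one(self, rng):
        x = rng.normal(size=100)
        t = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        assert decorrelate_variables(t) == ["a", "c"]

    def test_independent_all_retained(self, rng):
        t = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        assert decorrelate_variables(t) == list("abcd")

    def test_nineteen_to_eight_structured_reduction(self, rng):
        # 8 independent drivers + 11 near-copies of earlier columns
        n = 300
        base = rng.normal(size=(n, 8))
        cols = {}
        order = []
        for i in range(8):
            cols[f"v{i:02d}"] = base[:, i]
            order.append(f"v{i:02d}")
        for j in range(11):
            src = j % 8
            cols[f"w{j:02d}"] = base[:, src] + rng.normal(0, 0.05, n)
            order.append(f"w{j:02d}")
        t = pd.DataFrame(cols)[order]
        retained = decorrelate_variables(t, r_threshold=0.8)
        assert retained == [f"v{i:02d}" for i in range(8)]

    def test_constant_variable_dropped_with_warning(self, rng):
        t = pd.DataFrame({"a": np.ones(50), "b": rng.normal(size=50),
                          "c": rng.normal(size=50)})
        with pytest.warns(UserWarning):
            retained = decorrelate_variables(t)
        assert retained == ["b", "c"]


class TestManova:
    def test_wilks_matches_hand_computation(self):
        # 2 groups x 3 points, 2 variables: E and H by hand
        x = np.array([
            [1.0, 2.0], [2.0, 1.0], [3.0, 3.0],   # group a
            [4.0, 5.0], [5.0, 7.0], [6.0, 6.0],   # group b
        ])
        g = np.array(["a"] * 3 + ["b"] * 3)
        lam, F, df, p = wilks_lambda(x, g)
        ma, mb = x[:3].mean(0), x[3:].mean(0)
        grand = x.mean(0)
        E = np.zeros((2, 2))
        for xi, m in ((x[:3], ma), (x[3:], mb)):
            d = xi - m
            E += d.T @ d
        H = 3 * np.outer(ma - grand, ma - grand) + 3 * np.outer(mb - grand, mb - grand)
        lam_hand = np.linalg.det(E) / np.linalg.det(E + H)
        assert lam == pytest.approx(lam_hand, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        x = rng.normal(size=(45, 3))
        x[15:30, 0] += 0.8
        g = np.repeat(["a", "b", "c"], 15)
        lam, F, df, p = wilks_lambda(x, g)
        frame = pd.DataFrame(x, columns=["x1", "x2", "x3"])
        frame["g"] = g
        tab = MANOVA.from_formula("x1 + x2 + x3 ~ g", data=frame).mv_test()
        stat = tab.results["g"]["stat"]
        assert lam == pytest.approx(float(stat.loc["Wilks' lambda", "Value"]), abs=1e-9)
        assert p == pytest.approx(float(stat.loc["Wilks' lambda", "Pr > F"]), abs=1e-9)

    def test_gross_separation(self, rng):
        x = rng.normal(size=(60, 2))
        x[30:, 0] += 5.0
        g = np.repeat(["a", "b"], 30)
        res = climate_pca_manova(pd.DataFrame(x, columns=["v1", "v2"]), g,
                                 variables=["v1", "v2"])
        assert res["p"] < 1e-6
        assert res["explained"].sum() <= 1 + 1e-12

    def test_type_i_error_calibrated(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=(36, 3))
            g = np.repeat(["a", "b", "c"], 12)
            _, _, _, p = wilks_lambda(x, g)
            hits += p < 0.05
        assert 0.02 <= hits / reps <= 0.08


class TestSuitability:
    def _group_climate(self, rng, mean, n=60):
        vals = rng.normal(mean, 1.0, size=(n, 2))
        return pd.DataFrame(vals, columns=["v1", "v2"])

    def _rasters(self):
        grid = np.linspace(-3, 9, 13)
        v1 = np.tile(grid, (13, 1))
        v2 = np.tile(grid[:, None], (1, 13))
        return {
            "v1": _raster(v1, "v1"), "v2": _raster(v2, "v2", cell=1.0),
        }

    def test_maximal_at_group_mean(self, rng):
        rasters = self._rasters()
        clim = self._group_climate(rng, 3.0)
        surf = suitability_surface(clim, rasters, variables=["v1", "v2"], group="g")
        # the raw envelope peaks (== ~1) at the cell whose climate is nearest
        # the group mean
        i, j = np.unravel_index(np.argmax(surf.raw), surf.raw.shape)
        mean_v1 = clim["v1"].mean()
        assert abs(rasters["v1"].values[i, j] - mean_v1) <= 1.0
        assert surf.raw.max() <= 1.0
        assert surf.prob.sum() == pytest.approx(1.0)

    def test_uniform_climate_uniform_surface(self, rng):
        rasters = {"v1": _raster(np.full((4, 4), 5.0))}
        clim = pd.DataFrame({"v1": rng.normal(5.0, 1.0, 30)})
        surf = suitability_surface(clim, rasters, variables=["v1"], group="g")
        np.testing.assert_allclose(surf.prob, 1.0 / 16)

    def test_own_niche_scores_higher(self, rng):
        rasters = self._rasters()
        for seed in range(5):
            r = np.random.default_rng(seed)
            ca = self._group_climate(r, 0.0)
            cb = self._group_climate(r, 6.0)
            sa = suitability_surface(ca, rasters, variables=["v1", "v2"], group="a")
            sb = suitability_surface(cb, rasters, variables=["v1", "v2"], group="b")
            # a's surface puts more mass where a's climate lives
            cell_a = rasters["v1"].cell_index(3.0 + 0.0, 3.0)
            low = sa.prob[np.abs(rasters["v1"].values - 6.0) < 1].sum()
            high = sa.prob[np.abs(rasters["v1"].values - 0.0) < 1].sum()
            assert high > low

    def test_needs_enough_occurrences(self):
        rasters = {"v1": _raster(np.ones((2, 2)))}
        clim = pd.DataFrame({"v1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            suitability_surface(clim, rasters, variables=["v1", "v1b"], group="g")


class TestSchoenersD:
    @staticmethod
    def _surface(prob, group="g"):
        prob = np.asarray(prob, float)
        return SuitabilitySurface(group=group, raw=prob, prob=prob / prob.sum(),
                                  xll=0.0, yll=0.0, cellsize=1.0)

    def test_identical_complete_overlap(self):
        s = self._surface([[0.25, 0.25], [0.25, 0.25]])
        assert schoeners_d(s, s) == pytest.approx(1.0)

    def test_disjoint_zero(self):
        s1 = self._surface([[1.0, 0.0], [0.0, 0.0]])
        s2 = self._surface([[0.0, 0.0], [0.0, 1.0]])
        assert schoeners_d(s1, s2) == pytest.approx(0.0)

    def test_hand_computed_half(self):
        s1 = self._surface([[0.5, 0.5], [0.0, 0.0]])
        s2 = self._surface([[0.0, 0.5], [0.5, 0.0]])
        assert schoeners_d(s1, s2) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = self._surface(rng.random((5, 5)))
        b = self._surface(rng.random((5, 5)))
        assert schoeners_d(a, b) == schoeners_d(b, a)

    def test_misaligned_rejected(self):
        s1 = self._surface([[1.0, 1.0]])
        s2 = SuitabilitySurface(group="g", raw=np.ones((1, 2)),
                                prob=np.full((1, 2), 0.5), xll=5.0, yll=0.0,
                                cellsize=1.0)
        with pytest.raises(ValueError):
            schoeners_d(s1, s2)

    def test_monotone_separation(self, rng):
        # increasing niche-centroid distance never increases expected D
        grid = np.linspace(-2, 14, 17)
        rasters = {"v1": _raster(np.tile(grid, (3, 1)))}
        mean_d = []
        for sep in (0.0, 3.0, 6.0, 9.0):
            ds = []
            for seed in range(5):
                r = np.random.default_rng(seed)
                ca = pd.DataFrame({"v1": r.normal(2.0, 1.0, 40)})
                cb = pd.DataFrame({"v1": r.normal(2.0 + sep, 1.0, 40)})
                sa = suitability_surface(ca, rasters, variables=["v1"], group="a")
                sb = suitability_surface(cb, rasters, variables=["v1"], group="b")
                ds.append(schoeners_d(sa, sb))
            mean_d.append(np.mean(ds))
        assert all(x >= y - 1e-9 for x, y in zip(mean_d, mean_d[1:]))
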