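"""Gridding, per-cell MDT, Kruskal-Wallis with enumeration oracle, Dunn
post hoc, and quadrant assignment."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from phylosdm.occurrences import OccurrenceRecord
from phylosdm.phylo import StemAgeTable
from phylosdm.rasters import RasterLayer
from phylosdm.spatial import (albers_project, assign_region, build_grid,
                              cell_mdt, classify_mdt, attach_suitability,
                              kruskal_wallis, pairwise_posthoc)


def _rec(x, y, sp):
    return OccurrenceRecord(sp, lat=y, lon=x)


class TestGrid:
    def test_single_point_one_cell(self):
        g = build_grid(np.array([[34.0, 61.0]]), 100)
        assert (g.n_rows, g.n_cols) == (1, 1)
        assert g.cell_of(34.0, 61.0) == (0, 0)

    def test_span_sets_shape(self):
        g = build_grid(np.array([[0.0, 0.0], [250.0, 150.0]]), 100)
        assert (g.n_rows, g.n_cols) == (2, 3)

    def test_every_point_in_exactly_one_cell(self):
        rng = np.random.default_rng(40)
        pts = rng.uniform(-500, 500, size=(200, 2))
        g = build_grid(pts, 100)
        for x, y in pts:
            row, col = g.cell_of(x, y)
            x0, y0, x1, y1 = g.cell_bounds(row, col)
            assert x0 <= x < x1 and y0 <= y < y1


class TestCellMDT:
    def test_mean_and_dedup(self):
        table = StemAgeTable({"a": 10.0, "b": 30.0})
        recs = [_rec(10, 10, "a"), _rec(20, 20, "b")] + \
            [_rec(30, 30, "a")] * 5
        g = build_grid(np.array([[r.lon, r.lat] for r in recs]), 100)
        cells = cell_mdt(g, recs, table)
        assert len(cells) == 1
        assert cells[0].species_present == {"a", "b"}
        assert cells[0].mdt == 20.0

    def test_missing_species_rejected(self):
        table = StemAgeTable({"a": 10.0})
        g = build_grid(np.array([[0.0, 0.0]]), 100)
        with pytest.raises(KeyError, match="missing"):
            cell_mdt(g, [_rec(0, 0, "zz")], table)


class TestClassifyMDT:
    def _cells(self, mdts):
        table = StemAgeTable({f"s{i}": m for i, m in enumerate(mdts)})
        recs = [_rec(100.0 * i + 1, 1.0, f"s{i}")
                for i in range(len(mdts))]
        g = build_grid(np.array([[r.lon, r.lat] for r in recs]), 100)
        return cell_mdt(g, recs, table)

    def test_clustered_mdts_separate_into_their_clusters(self):
        mdts = [5, 6, 7, 40, 41, 42, 80, 81, 82, 120, 121, 122]
        cells = self._cells(mdts)
        breaks = classify_mdt(cells, 4)
        assert breaks == [7.0, 42.0, 82.0]
        for c in cells:
            assert c.mdt_class == 1 + int(np.digitize(c.mdt, breaks,
                                                      right=True))

    def test_identical_mdts_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            classify_mdt(self._cells([5.0] * 6), 4)

    def test_classes_monotone_in_mdt(self):
        rng = np.random.default_rng(41)
        cells = self._cells(rng.uniform(1, 100, size=15).tolist())
        classify_mdt(cells, 4)
        by_mdt = sorted(cells, key=lambda c: c.mdt)
        classes = [c.mdt_class for c in by_mdt]
        assert classes == sorted(classes)


class TestAttachSuitability:
    def test_uniform_map_gives_top_class(self):
        suit = RasterLayer("s", np.full((10, 10), 0.9), (0, 0, 10.0, 10.0))
        table = StemAgeTable({"a": 5.0})
        recs = [_rec(15, 15, "a"), _rec(85, 85, "a")]
        g = build_grid(np.array([[r.lon, r.lat] for r in recs]), 50)
        cells = cell_mdt(g, recs, table)
        attach_suitability(cells, g, suit, (0.18, 0.45, 0.68))
        assert all(c.suitability_class == 4 for c in cells)
        assert all(c.suitability_value == pytest.approx(0.9) for c in cells)

    def test_mixed_cell_mean_then_classify(self):
        vals = np.zeros((2, 2))
        vals[:, 0] = 0.1   # west half
        vals[:, 1] = 0.9   # east half
        suit = RasterLayer("s", vals, (0, 0, 50.0, 50.0))
        table = StemAgeTable({"a": 5.0})
        recs = [_rec(50, 50, "a")]
        g = build_grid(np.array([[0.0, 0.0], [99.0, 99.0]]), 100)
        cells = cell_mdt(g, recs, table)
        attach_suitability(cells, g, suit, (0.18, 0.45, 0.68))
        assert cells[0].suitability_value == pytest.approx(0.5)
        assert cells[0].suitability_class == 3

    def test_uncovered_cell_flagged(self):
        suit = RasterLayer("s", np.full((2, 2), 0.5), (0, 0, 10.0, 10.0))
        table = StemAgeTable({"a": 5.0})
        recs = [_rec(500, 500, "a")]
        g = build_grid(np.array([[r.lon, r.lat] for r in recs]), 100)
        cells = cell_mdt(g, recs, table)
        attach_suitability(cells, g, suit, (0.18, 0.45, 0.68))
        assert cells[0].suitability_class is None


def enumerate_kw_p(groups):
    """Oracle: exact permutation p for the tie-corrected H by direct rank
    arithmetic over all distinct assignments."""
    def h_of(parts):
        pooled = np.concatenate(parts)
        n = len(pooled)
        ranks = stats.rankdata(pooled)
        start, total = 0, 0.0
        for g in parts:
            r = ranks[start:start + len(g)]
            total += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12.0 / (n * (n + 1)) * total - 3 * (n + 1)
        _, counts = np.unique(pooled, return_counts=True)
        tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
        return h / tie if tie > 0 else 0.0

    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    h_obs = h_of([np.asarray(g, float) for g in groups])
    idx = range(len(pooled))
    count = total = 0
    for perm in itertools.permutations(idx):
        parts, start = [], 0
        for s in sizes:
            parts.append(pooled[list(perm[start:start + s])])
            start += s
        count += h_of(parts) >= h_obs - 1e-12
        total += 1
    return h_obs, count / total


class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.H == 0.0 and res.p_value == 1.0

    def test_textbook_example_h_and_permutation_p(self):
        res = kruskal_wallis([[1, 2, 3], [10, 11, 12]], permutation=True)
        assert res.H == pytest.approx(3.857142857, abs=1e-9)
        assert res.p_value == pytest.approx(0.1)
        assert res.df == 1

    def test_chi_square_p_matches_scipy(self):
        groups = [[1.0, 5.0, 8.0], [2.0, 9.0], [3.0, 3.0, 7.0]]
        res = kruskal_wallis(groups)
        h, p = stats.kruskal(*groups)
        assert res.H == pytest.approx(h) and res.p_value == pytest.approx(p)

    def test_permutation_p_matches_enumeration_up_to_n8(self):
        rng = np.random.default_rng(42)
        for sizes in ([3, 3], [2, 3, 3], [2, 2, 2], [4, 4], [2, 2, 2, 2]):
            vals = rng.integers(0, 6, size=sum(sizes)).astype(float)
            groups, start = [], 0
            for s in sizes:
                groups.append(vals[start:start + s].tolist())
                start += s
            if np.ptp(vals) == 0:
                continue
            h_want, p_want = enumerate_kw_p(groups)
            res = kruskal_wallis(groups, permutation=True)
            assert res.H == pytest.approx(h_want, abs=1e-9)
            assert res.p_value == pytest.approx(p_want, abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        groups = [[1.0, 4.0, 9.0], [2.0, 25.0], [16.0, 36.0, 49.0]]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([[math.sqrt(v) for v in g] for g in groups])
        assert a.H == pytest.approx(b.H) and \
            a.p_value == pytest.approx(b.p_value)


class TestPosthoc:
    def test_two_groups_single_unadjusted_comparison(self):
        groups = [[1.0, 2.0, 3.0, 4.0], [6.0, 7.0, 8.0, 9.0]]
        (i, j, z, p, sig), = pairwise_posthoc(groups)
        assert (i, j) == (0, 1)
        # with one comparison Holm leaves p untouched; z maps to the
        # chi-square KW statistic via z^2 = H
        res = kruskal_wallis(groups)
        assert z ** 2 == pytest.approx(res.H, abs=1e-9)
        assert p == pytest.approx(res.p_value, abs=1e-9)

    def test_adjusted_p_monotone_above_raw(self):
        rng = np.random.default_rng(43)
        groups = [rng.uniform(0, 1, size=6).tolist(),
                  (rng.uniform(0, 1, size=6) + 0.5).tolist(),
                  (rng.uniform(0, 1, size=6) + 1.0).tolist()]
        results = pairwise_posthoc(groups)
        pooled = np.concatenate(groups)
        n = len(pooled)
        base_var = n * (n + 1) / 12.0
        for i, j, z, p_adj, _ in results:
            se = math.sqrt(base_var * (1 / len(groups[i])
                                       + 1 / len(groups[j])))
            raw = 2 * stats.norm.sf(abs(z))
            assert p_adj >= raw - 1e-12

    def test_planted_shift_detected_with_power(self):
        rng = np.random.default_rng(44)
        flagged = 0
        for _ in range(100):
            low = rng.normal(10, 5, size=12)
            high = rng.normal(40, 5, size=12)
            mid1 = rng.normal(20, 5, size=12)
            mid2 = rng.normal(25, 5, size=12)
            results = pairwise_posthoc([low, mid1, mid2, high])
            hit = any(sig for i, j, _, _, sig in results
                      if (i, j) == (0, 3))
            flagged += hit
        assert flagged >= 90


class TestRegions:
    LINE_WE = [(50.0, 0.0), (50.0, 100.0)]   # south-to-north vertical
    LINE_NS = [(0.0, 50.0), (100.0, 50.0)]   # west-to-east horizontal

    @pytest.mark.parametrize("point,expect", [
        ((10, 90), "NW"), ((90, 90), "NE"),
        ((10, 10), "SW"), ((90, 10), "SE"),
    ])
    def test_quadrants(self, point, expect):
        assert assign_region(point, self.LINE_WE, self.LINE_NS) == expect

    def test_on_line_ties_go_east_and_south(self):
        assert assign_region((50, 50), self.LINE_WE, self.LINE_NS) == "SE"

    def test_every_point_gets_exactly_one_label(self):
        rng = np.random.default_rng(45)
        for x, y in rng.uniform(0, 100, size=(50, 2)):
            label = assign_region((x, y), self.LINE_WE, self.LINE_NS)
            assert label in {"NE", "NW", "SE", "SW"}

    def test_label_invariant_to_polyline_densification(self):
        # a jagged north-east trending divider
        coarse = [(0.0, 0.0), (30.0, 40.0), (60.0, 70.0), (100.0, 100.0)]
        dense = []
        for (x0, y0), (x1, y1) in zip(coarse[:-1], coarse[1:]):
            for f in np.linspace(0, 1, 11)[:-1]:
                dense.append((x0 + f * (x1 - x0), y0 + f * (y1 - y0)))
        dense.append(coarse[-1])
        rng = np.random.default_rng(46)
        for x, y in rng.uniform(5, 95, size=(40, 2)):
            if abs(y - np.interp(x, [c[0] for c in coarse],
                                 [c[1] for c in coarse])) < 2:
                continue  # skip points hugging the divider
            assert assign_region((x, y), coarse, self.LINE_NS) == \
                assign_region((x, y), dense, self.LINE_NS)


def test_albers_preserves_area_locally():
    # a 1-degree cell near the standard parallels maps to a quadrilateral
    # whose area is close to its spherical area
    lat, lon = 30.0, 110.0
    corners = [(lat, lon), (lat, lon + 1), (lat + 1, lon + 1),
               (lat + 1, lon)]
    xs, ys = albers_project([c[0] for c in corners],
                            [c[1] for c in corners])
    area = 0.5 * abs(sum(xs[i] * ys[(i + 1) % 4] - xs[(i + 1) % 4] * ys[i]
                         for i in range(4)))
    R = 6371.0088
    spherical = (R ** 2 * math.radians(1.0)
                 * (math.sin(math.radians(lat + 1))
                    - math.sin(math.radians(lat))))
    assert area == pytest.approx(spherical, rel=1e-3)
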