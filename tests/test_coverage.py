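import numpy as np
import pytest
from shapely.geometry import box

from biodisagg.coverage import (
    ProtectedAreaRecord,
    SiteRecord,
    UnitGeometry,
    dissolve,
    pa_coverage,
    site_coverage,
)

# ---------------------------------------------------------------------------
# rasterization oracle: percentage of a rectangular frame covered by any of a
# set of axis-aligned rectangles, counted on an n x n grid of cell centres.
# Pure index arithmetic — no geometry library involved.


def raster_pct(frame_bounds, rects, n=1000):
    fx0, fy0, fx1, fy1 = frame_bounds
    xs = fx0 + (np.arange(n) + 0.5) * (fx1 - fx0) / n
    ys = fy0 + (np.arange(n) + 0.5) * (fy1 - fy0) / n
    covered = np.zeros((n, n), dtype=bool)
    for rx0, ry0, rx1, ry1 in rects:
        ix = (xs >= rx0) & (xs <= rx1)
        iy = (ys >= ry0) & (ys <= ry1)
        covered |= np.outer(ix, iy)
    return 100.0 * covered.mean()


def random_rects(rng, frame, k, scale=0.5):
    fx0, fy0, fx1, fy1 = frame
    w, h = fx1 - fx0, fy1 - fy0
    rects = []
    for _ in range(k):
        rw, rh = rng.uniform(0.05, scale, 2) * (w, h)
        x = rng.uniform(fx0 - rw / 2, fx1 - rw / 2)
        y = rng.uniform(fy0 - rh / 2, fy1 - rh / 2)
        rects.append((x, y, x + rw, y + rh))
    return rects


class TestDissolve:
    def test_disjoint_squares_add(self):
        u = dissolve([box(0, 0, 1, 1), box(2, 0, 3, 1)])
        assert u.area == pytest.approx(2.0)

    def test_identical_squares_union_once(self):
        u = dissolve([box(0, 0, 1, 1), box(0, 0, 1, 1)])
        assert u.area == pytest.approx(1.0)

    def test_empty_input(self):
        assert dissolve([]).is_empty

    def test_union_never_exceeds_sum(self):
        rng = np.random.default_rng(5)
        rects = random_rects(rng, (0, 0, 10, 10), 8)
        geoms = [box(*r) for r in rects]
        assert dissolve(geoms).area <= sum(g.area for g in geoms) + 1e-9

    def test_invalid_geometry_repaired(self):
        from shapely.geometry import Polygon

        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])  # self-intersecting
        assert not bowtie.is_valid
        u = dissolve([bowtie])
        assert u.is_valid and u.area > 0

    def test_invalid_geometry_rejected_when_configured(self):
        from shapely.geometry import Polygon

        from biodisagg.coverage import InvalidGeometryError

        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(InvalidGeometryError):
            dissolve([bowtie], on_invalid="reject")


class TestSiteCoverage:
    def unit(self):
        return UnitGeometry("U", land=box(0, 0, 1, 1), sea=None)

    def test_half_covered(self):
        sites = [SiteRecord("s1", "IBA", box(0, 0, 0.5, 1))]
        stat = site_coverage(sites, self.unit(), "IBA")
        assert stat.pct_cover == pytest.approx(50.0)
        assert stat.n_sites == 1
        assert stat.mean_size == pytest.approx(0.5)

    def test_zero_sites(self):
        stat = site_coverage([], self.unit(), "AZE")
        assert stat.n_sites == 0
        assert stat.mean_size is None
        assert stat.pct_cover == 0.0

    def test_empty_unit_geometry_not_applicable(self):
        sites = [SiteRecord("s1", "IBA", box(0, 0, 1, 1))]
        stat = site_coverage(sites, UnitGeometry("empty"), "IBA")
        assert stat.pct_cover is None

    def test_straddling_site_counted_once_by_representative_point(self):
        left = UnitGeometry("L", land=box(0, 0, 1, 1))
        right = UnitGeometry("R", land=box(1, 0, 2, 1))
        # site straddles the shared boundary; representative point in one
        sites = [SiteRecord("s", "IBA", box(0.8, 0.2, 1.3, 0.8))]
        n_total = sum(
            site_coverage(sites, u, "IBA").n_sites for u in (left, right)
        )
        assert n_total == 1
        # ...but both units see partial percentage cover
        for u in (left, right):
            assert site_coverage(sites, u, "IBA").pct_cover > 0

    def test_matches_rasterization_oracle(self):
        rng = np.random.default_rng(11)
        frame = (0, 0, 10, 10)
        for _ in range(3):
            rects = random_rects(rng, frame, 6)
            sites = [
                SiteRecord(f"s{i}", "IBA", box(*r)) for i, r in enumerate(rects)
            ]
            stat = site_coverage(sites, UnitGeometry("U", land=box(*frame)), "IBA")
            assert stat.pct_cover == pytest.approx(
                raster_pct(frame, rects), abs=1.0
            )


class TestPaCoverage:
    def unit(self):
        return UnitGeometry("U", land=box(0, 0, 1, 1), sea=box(1, 0, 2, 1))

    def pa(self, pa_id, geom, realm="terrestrial", year=2000):
        return ProtectedAreaRecord(pa_id, "AAA", realm, geom, year)

    def test_full_land_cover(self):
        pct_land, _ = pa_coverage([self.pa("p", box(0, 0, 1, 1))], self.unit())
        assert pct_land == pytest.approx(100.0)

    def test_nested_pas_same_as_outer(self):
        outer = self.pa("o", box(0, 0, 0.8, 1))
        inner = self.pa("i", box(0.2, 0.2, 0.5, 0.5))
        both_land, _ = pa_coverage([outer, inner], self.unit())
        outer_land, _ = pa_coverage([outer], self.unit())
        assert both_land == pytest.approx(outer_land)

    def test_no_sea_not_applicable(self):
        unit = UnitGeometry("U", land=box(0, 0, 1, 1))
        _, pct_sea = pa_coverage([self.pa("p", box(0, 0, 1, 1))], unit)
        assert pct_sea is None

    def test_realms_kept_separate(self):
        marine = self.pa("m", box(1, 0, 2, 1), realm="marine")
        pct_land, pct_sea = pa_coverage([marine], self.unit())
        assert pct_land == 0.0
        assert pct_sea == pytest.approx(100.0)

    def test_point_only_records_excluded_by_default(self):
        from shapely.geometry import Point

        pt = ProtectedAreaRecord("pt", "AAA", "terrestrial", Point(0.5, 0.5), 2000, 0.3)
        pct_land, _ = pa_coverage([pt], self.unit())
        assert pct_land == 0.0
        pct_land_buf, _ = pa_coverage([pt], self.unit(), point_buffer_mode=True)
        assert pct_land_buf > 0.0

    def test_adding_pa_is_monotone(self):
        rng = np.random.default_rng(3)
        unit = self.unit()
        pas = []
        last = 0.0
        for i, r in enumerate(random_rects(rng, (0, 0, 1, 1), 6, scale=0.4)):
            pas.append(self.pa(f"p{i}", box(*r)))
            pct, _ = pa_coverage(pas, unit)
            assert pct >= last - 1e-12
            last = pct

    def test_matches_rasterization_oracle(self):
        rng = np.random.default_rng(12)
        land = (0, 0, 5, 5)
        rects = random_rects(rng, land, 7)
        pas = [self.pa(f"p{i}", box(*r)) for i, r in enumerate(rects)]
        unit = UnitGeometry("U", land=box(*land))
        pct_land, _ = pa_coverage(pas, unit)
        assert pct_land == pytest.approx(raster_pct(land, rects), abs=1.0)


def test_subregion_dissolved_areas_partition_region(world):
    """Total dissolved site area over the subregions that partition a
    region equals the region's dissolved site area (boundaries may split
    sites, but area is conserved)."""
    from shapely.ops import unary_union

    scheme = world.schemes["GEO"]
    geoms = world.unit_geometries["GEO"]
    merged = unary_union([s.geometry for s in world.sites if s.site_type == "IBA"])
    for region in scheme.units("region", include_special=False):
        region_area = merged.intersection(geoms[region].total).area
        subs = [
            s
            for s in scheme.units("subregion", include_special=False)
            if scheme.region_of_subregion(s) == region
        ]
        sub_area = sum(merged.intersection(geoms[s].total).area for s in subs)
        assert sub_area == pytest.approx(region_area, rel=1e-9, abs=1e-9)


def test_pipeline_coverage_matches_generator_truth(world):
    import pandas as pd

    from biodisagg.coverage import tabulate_pa_coverage, tabulate_site_coverage

    for sname, scheme in world.schemes.items():
        ubl = {lvl: scheme.units(lvl) for lvl in ("region", "subregion")}
        geoms = world.unit_geometries[sname]
        got = tabulate_site_coverage(world.sites, geoms, ubl)
        m = got.merge(
            world.truth.site_stats[sname],
            on=["unit", "level", "site_type"],
            suffixes=("", "_t"),
        )
        assert len(m) == len(got)
        assert (m.n == m.n_t).all()
        np.testing.assert_allclose(
            m.pct_cover.astype(float), m.pct_cover_t.astype(float), atol=1e-9
        )
        mean_pairs = m[["mean_size_km2", "mean_size_km2_t"]].astype(float)
        assert ((mean_pairs.isna().all(axis=1)) | (
            (mean_pairs.mean_size_km2 - mean_pairs.mean_size_km2_t).abs() < 1e-9
        )).all()

        gotp = tabulate_pa_coverage(world.pas, geoms, ubl)
        mp = gotp.merge(
            world.truth.pa_stats[sname], on=["unit", "level"], suffixes=("", "_t")
        )
        assert len(mp) == len(gotp)
        for c in ("pct_land", "pct_sea"):
            a = mp[c].astype(float).fillna(-1)
            b = mp[c + "_t"].astype(float).fillna(-1)
            np.testing.assert_allclose(a, b, atol=1e-9)
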