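"""Dissolved-polygon coverage statistics for sites and protected areas.

Overlapping polygons are *dissolved* (unioned) before any area is
measured, so overlap is never double-counted.  Three statistics are
produced per spatial unit: counts and mean sizes of important sites
(IBAs and AZE sites), percentage of the unit covered by each site layer,
and percentage of the unit's land and sea covered by terrestrial and
marine protected areas respectively.

Geometries are treated as planar; callers working in geographic
coordinates should pass an equal-area projection callable via
``transform``.  A site is *counted* in the unit containing its
representative interior point (so sites straddling boundaries count
once), whereas percentage coverage always uses true geometric
intersection with the unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

__all__ = [
    "SiteRecord",
    "ProtectedAreaRecord",
    "UnitGeometry",
    "CoverageStat",
    "InvalidGeometryError",
    "dissolve",
    "site_coverage",
    "pa_coverage",
    "tabulate_site_coverage",
    "tabulate_pa_coverage",
]

SITE_TYPES = ("IBA", "AZE")
REALMS = ("terrestrial", "marine")


class InvalidGeometryError(ValueError):
    """A geometry is invalid and could not be repaired."""


def _repair(geom: BaseGeometry, on_invalid: str = "repair") -> BaseGeometry | None:
    """Attempt zero-buffer/make_valid repair once; None means 'drop'."""
    if geom.is_valid:
        return geom
    if on_invalid == "reject":
        raise InvalidGeometryError("invalid geometry rejected by configuration")
    fixed = make_valid(geom)
    if fixed.is_valid and not fixed.is_empty:
        logger.warning("repaired one invalid geometry")
        return fixed
    logger.warning("dropped one unrepairable geometry")
    return None


@dataclass
class SiteRecord:
    """An important site (IBA or AZE) with its polygon."""

    site_id: str
    site_type: str
    geometry: BaseGeometry
    realm: str = "terrestrial"

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise InvalidGeometryError(f"site {self.site_id}: empty geometry")

    @property
    def area(self) -> float:
        return self.geometry.area


@dataclass
class ProtectedAreaRecord:
    pa_id: str
    country_code: str
    realm: str
    geometry: BaseGeometry | None
    year_established: int | None = None
    reported_area: float | None = None  # for point-only records

    def __post_init__(self) -> None:
        if self.realm not in REALMS:
            raise ValueError(f"realm must be one of {REALMS}")

    @property
    def is_polygonal(self) -> bool:
        return self.geometry is not None and self.geometry.area > 0


@dataclass
class UnitGeometry:
    """Land/sea split of one spatial unit; either part may be empty."""

    unit_label: str
    land: BaseGeometry | None = None
    sea: BaseGeometry | None = None

    @property
    def total(self) -> BaseGeometry | None:
        parts = [g for g in (self.land, self.sea) if g is not None and not g.is_empty]
        if not parts:
            return None
        return unary_union(parts)


@dataclass
class CoverageStat:
    unit_label: str
    n_sites: int
    mean_size: float | None  # None when n_sites == 0
    pct_cover: float | None  # None when the unit geometry is empty


def dissolve(
    geometries: Iterable[BaseGeometry], on_invalid: str = "repair"
) -> BaseGeometry:
    """Union a collection into one geometry (empty union for no inputs)."""
    kept = []
    for g in geometries:
        r = _repair(g, on_invalid)
        if r is not None and not r.is_empty:
            kept.append(r)
    return unary_union(kept)


def _polygonal_pas(
    pas: Sequence[ProtectedAreaRecord],
    point_buffer_mode: bool = False,
) -> list[BaseGeometry]:
    """Geometries entering coverage; point-only records excluded by default.

    With ``point_buffer_mode`` a point record with a reported area is
    replaced by a circle of that area centred on the point.
    """
    geoms: list[BaseGeometry] = []
    n_points = 0
    for pa in pas:
        if pa.is_polygonal:
            geoms.append(pa.geometry)
        elif point_buffer_mode and pa.geometry is not None and pa.reported_area:
            radius = (pa.reported_area / 3.141592653589793) ** 0.5
            geoms.append(pa.geometry.buffer(radius))
        else:
            n_points += 1
    if n_points:
        logger.info("excluded %d point-only protected-area records", n_points)
    return geoms


def site_coverage(
    sites: Sequence[SiteRecord],
    unit_geometry: UnitGeometry,
    site_type: str,
    *,
    transform: Callable[[BaseGeometry], BaseGeometry] | None = None,
) -> CoverageStat:
    """Count, mean size and percentage cover of one site layer in one unit.

    Counts and mean sizes use representative-point assignment; the
    percentage uses the dissolved intersection of the sites with the
    unit, over the unit's land+sea area.
    """
    tf = transform or (lambda g: g)
    unit_total = unit_geometry.total
    typed = [s for s in sites if s.site_type == site_type]

    if unit_total is None or unit_total.is_empty:
        return CoverageStat(unit_geometry.unit_label, 0, None, None)

    # contains (not intersects): a representative point exactly on a shared
    # boundary would otherwise be double-counted by adjacent units
    inside = [s for s in typed if unit_total.contains(s.geometry.representative_point())]
    n = len(inside)
    mean_size = (
        sum(tf(s.geometry).area for s in inside) / n if n else None
    )

    clipped = [s.geometry.intersection(unit_total) for s in typed]
    merged = dissolve(g for g in clipped if not g.is_empty)
    pct = 100.0 * tf(merged).area / tf(unit_total).area
    return CoverageStat(unit_geometry.unit_label, n, mean_size, min(pct, 100.0))


def pa_coverage(
    pas: Sequence[ProtectedAreaRecord],
    unit_geometry: UnitGeometry,
    *,
    transform: Callable[[BaseGeometry], BaseGeometry] | None = None,
    point_buffer_mode: bool = False,
) -> tuple[float | None, float | None]:
    """(pct_land, pct_sea) protected in one unit; None where no land/sea."""
    tf = transform or (lambda g: g)
    out: list[float | None] = []
    for realm, base in (("terrestrial", unit_geometry.land), ("marine", unit_geometry.sea)):
        if base is None or base.is_empty:
            out.append(None)
            continue
        geoms = _polygonal_pas([p for p in pas if p.realm == realm], point_buffer_mode)
        merged = dissolve(geoms)
        pct = 100.0 * tf(merged.intersection(base)).area / tf(base).area
        out.append(min(pct, 100.0))
    return out[0], out[1]


def tabulate_site_coverage(
    sites: Sequence[SiteRecord],
    unit_geometries: dict[str, UnitGeometry],
    units_by_level: dict[str, list[str]],
    **kwargs,
) -> pd.DataFrame:
    """Rows (unit, level, site_type, n, mean_size_km2, pct_cover)."""
    rows = []
    for level, units in units_by_level.items():
        for u in units:
            ug = unit_geometries.get(u)
            if ug is None:
                continue
            for st in SITE_TYPES:
                stat = site_coverage(sites, ug, st, **kwargs)
                rows.append(
                    {
                        "unit": u,
                        "level": level,
                        "site_type": st,
                        "n": stat.n_sites,
                        "mean_size_km2": stat.mean_size,
                        "pct_cover": stat.pct_cover,
                    }
                )
    return pd.DataFrame(rows)


def tabulate_pa_coverage(
    pas: Sequence[ProtectedAreaRecord],
    unit_geometries: dict[str, UnitGeometry],
    units_by_level: dict[str, list[str]],
    **kwargs,
) -> pd.DataFrame:
    """Rows (unit, level, pct_land, pct_sea)."""
    rows = []
    for level, units in units_by_level.items():
        for u in units:
            ug = unit_geometries.get(u)
            if ug is None:
                continue
            pct_land, pct_sea = pa_coverage(pas, ug, **kwargs)
            rows.append(
                {"unit": u, "level": level, "pct_land": pct_land, "pct_sea": pct_sea}
            )
    return pd.DataFrame(rows)
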