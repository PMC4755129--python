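"""Interchange-file readers/writers and product assembly.

Tabular inputs and outputs are CSV (RFC-4180, "." decimal).  Every
product file starts with one "#"-prefixed metadata comment line carrying
the tool version, seed and threshold, followed by the header row.
Percentages are serialized to one decimal place, counts as integers, and
not-applicable values as empty fields.  Geometries travel as GeoJSON
FeatureCollections read and written with shapely.

Product files follow the ``<Product>_<SCHEME>.csv`` naming convention:
Total_Species, Endemic_Species, Red_List_Index, IBAs_AZEs, PAs,
Protected_IBAs and Protected_AZEs — seven per scheme.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from . import __version__
from .coverage import ProtectedAreaRecord, SiteRecord, UnitGeometry
from .regions import RegionScheme, UnitLevel, load_scheme
from .rli import AssessmentPeriod

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_csv",
    "write_csv",
    "read_sites",
    "write_sites",
    "read_pas",
    "write_pas",
    "read_unit_geometries",
    "write_unit_geometries",
    "write_world",
    "read_world_dir",
    "write_products",
]

PCT_COLUMNS = frozenset(
    {"pct_lower", "pct_best", "pct_upper", "pct_cover", "pct_land", "pct_sea",
     "median_pct", "ci_low", "ci_high"}
)
COUNT_COLUMNS = frozenset(
    {"EX", "EW", "CR", "EN", "VU", "NT", "LC", "DD", "NE", "total", "n", "year",
     "n_countries"}
)


class SchemaError(ValueError):
    """Aggregated input-validation failure (file, row, column named)."""


# -- CSV ---------------------------------------------------------------------


def write_csv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a product CSV with one leading metadata comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"biodisagg {__version__}", **(meta or {})}
    out = df.copy()
    for col in out.columns:
        if col in PCT_COLUMNS:
            out[col] = out[col].map(
                lambda v: "" if v is None or pd.isna(v) else f"{v:.1f}"
            )
        elif col in COUNT_COLUMNS:
            out[col] = out[col].map(
                lambda v: "" if v is None or pd.isna(v) else str(int(v))
            )
    with open(path, "w", encoding="utf-8", newline="") as f:
        f.write("# " + " ".join(f"{k}={v}" for k, v in meta.items()) + "\n")
        out.to_csv(f, index=False)


def read_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return df


# -- GeoJSON -----------------------------------------------------------------


def _read_features(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as f:
        gj = json.load(f)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    return gj["features"]


def _write_features(features: list[dict], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as f:
        json.dump({"type": "FeatureCollection", "features": features}, f)


def read_sites(path: str | Path) -> list[SiteRecord]:
    sites = []
    for i, feat in enumerate(_read_features(path)):
        props = feat.get("properties", {})
        try:
            sites.append(
                SiteRecord(
                    site_id=str(props["site_id"]),
                    site_type=str(props["site_type"]),
                    geometry=shape(feat["geometry"]),
                    realm=str(props.get("realm", "terrestrial")),
                )
            )
        except KeyError as e:
            raise SchemaError(f"{path}: feature {i} missing property {e}") from None
    return sites


def write_sites(sites: list[SiteRecord], path: str | Path) -> None:
    _write_features(
        [
            {
                "type": "Feature",
                "geometry": mapping(s.geometry),
                "properties": {
                    "site_id": s.site_id,
                    "site_type": s.site_type,
                    "realm": s.realm,
                },
            }
            for s in sites
        ],
        path,
    )


def read_pas(path: str | Path) -> list[ProtectedAreaRecord]:
    pas = []
    for i, feat in enumerate(_read_features(path)):
        props = feat.get("properties", {})
        try:
            year = props.get("year_established")
            pas.append(
                ProtectedAreaRecord(
                    pa_id=str(props["pa_id"]),
                    country_code=str(props["country_code"]),
                    realm=str(props["realm"]),
                    geometry=shape(feat["geometry"]) if feat.get("geometry") else None,
                    year_established=int(year) if year is not None else None,
                    reported_area=props.get("reported_area"),
                )
            )
        except KeyError as e:
            raise SchemaError(f"{path}: feature {i} missing property {e}") from None
    return pas


def write_pas(pas: list[ProtectedAreaRecord], path: str | Path) -> None:
    _write_features(
        [
            {
                "type": "Feature",
                "geometry": mapping(p.geometry) if p.geometry is not None else None,
                "properties": {
                    "pa_id": p.pa_id,
                    "country_code": p.country_code,
                    "realm": p.realm,
                    "year_established": p.year_established,
                    "reported_area": p.reported_area,
                },
            }
            for p in pas
        ],
        path,
    )


def read_unit_geometries(path: str | Path) -> dict[str, UnitGeometry]:
    """Features carry properties ``unit`` and ``part`` ("land" or "sea")."""
    out: dict[str, UnitGeometry] = {}
    for i, feat in enumerate(_read_features(path)):
        props = feat.get("properties", {})
        try:
            unit, part = str(props["unit"]), str(props["part"])
        except KeyError as e:
            raise SchemaError(f"{path}: feature {i} missing property {e}") from None
        geom = shape(feat["geometry"])
        ug = out.setdefault(unit, UnitGeometry(unit))
        if part == "land":
            ug.land = geom
        elif part == "sea":
            ug.sea = geom
        else:
            raise SchemaError(f"{path}: feature {i}: part must be 'land' or 'sea'")
    return out


def write_unit_geometries(geoms: dict[str, UnitGeometry], path: str | Path) -> None:
    feats = []
    for unit, ug in geoms.items():
        for part, g in (("land", ug.land), ("sea", ug.sea)):
            if g is not None and not g.is_empty:
                feats.append(
                    {
                        "type": "Feature",
                        "geometry": mapping(g),
                        "properties": {"unit": unit, "part": part},
                    }
                )
    _write_features(feats, path)


# -- world directory ---------------------------------------------------------


@dataclass
class WorldBundle:
    """On-disk world: everything the analysis commands consume."""

    schemes: dict[str, RegionScheme]
    assessments: pd.DataFrame
    occurrences: pd.DataFrame
    changes: pd.DataFrame
    range_fractions: pd.DataFrame
    sites: list[SiteRecord]
    pas: list[ProtectedAreaRecord]
    unit_geometries: dict[str, dict[str, UnitGeometry]]
    period: AssessmentPeriod
    years: list[int]
    manifest: dict


def write_world(world, out_dir: str | Path) -> Path:
    """Serialize a generated world into the directory layout the CLI reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.assessments.to_csv(out / "assessments.csv", index=False)
    world.occurrences.to_csv(out / "occurrences.csv", index=False)
    world.changes.to_csv(out / "changes.csv", index=False)
    world.range_fractions.to_csv(out / "range_fractions.csv", index=False)
    for name, scheme in world.schemes.items():
        scheme.to_frame().to_csv(out / f"scheme_{name}.csv", index=False)
        write_unit_geometries(world.unit_geometries[name], out / f"units_{name}.geojson")
    write_sites(world.sites, out / "sites.geojson")
    write_pas(world.pas, out / "pas.geojson")
    manifest = {
        "schemes": list(world.schemes),
        "period": [world.period.start_year, world.period.end_year],
        "years": [world.years[0], world.years[-1]],
        "seed": world.spec.seed,
        "threshold": world.spec.threshold,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as f:
        json.dump(manifest, f, indent=1)
    return out


def read_world_dir(world_dir: str | Path) -> WorldBundle:
    """Load a world directory, aggregating validation problems."""
    d = Path(world_dir)
    errors: list[str] = []

    def _try(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (SchemaError, FileNotFoundError, ValueError) as e:
            errors.append(str(e))
            return None

    with open(d / "manifest.json", encoding="utf-8") as f:
        manifest = json.load(f)
    assessments = _try(
        read_csv, d / "assessments.csv", required=["species_id", "group", "category"]
    )
    occurrences = _try(
        read_csv, d / "occurrences.csv", required=["species_id", "unit_code", "origin"]
    )
    changes = _try(
        read_csv,
        d / "changes.csv",
        required=["species_id", "cat_start", "cat_end", "genuine"],
    )
    fractions = _try(
        read_csv,
        d / "range_fractions.csv",
        required=["scheme", "level", "species_id", "unit", "fraction"],
    )
    schemes, unit_geoms = {}, {}
    for name in manifest["schemes"]:
        sch = _try(load_scheme, d / f"scheme_{name}.csv", name=name)
        if sch is not None:
            schemes[name] = sch
        ug = _try(read_unit_geometries, d / f"units_{name}.geojson")
        if ug is not None:
            unit_geoms[name] = ug
    sites = _try(read_sites, d / "sites.geojson")
    pas = _try(read_pas, d / "pas.geojson")
    if errors:
        raise SchemaError("; ".join(errors))
    y0, y1 = manifest["years"]
    return WorldBundle(
        schemes=schemes,
        assessments=assessments,
        occurrences=occurrences,
        changes=changes,
        range_fractions=fractions,
        sites=sites,
        pas=pas,
        unit_geometries=unit_geoms,
        period=AssessmentPeriod(*manifest["period"]),
        years=list(range(y0, y1 + 1)),
        manifest=manifest,
    )


# -- products ----------------------------------------------------------------

PRODUCT_PATTERNS = (
    "Total_Species_{scheme}.csv",
    "Endemic_Species_{scheme}.csv",
    "Red_List_Index_{scheme}.csv",
    "IBAs_AZEs_{scheme}.csv",
    "PAs_{scheme}.csv",
    "Protected_IBAs_{scheme}.csv",
    "Protected_AZEs_{scheme}.csv",
)


def write_products(
    results: dict[str, pd.DataFrame], out_dir: str | Path, meta: dict | None = None
) -> list[Path]:
    """Write one CSV per product; keys are final file stems."""
    out_dir = Path(out_dir)
    paths = []
    for name, df in results.items():
        p = out_dir / f"{name}.csv"
        write_csv(df, p, meta)
        paths.append(p)
        logger.info("wrote %s (%d rows)", p, len(df))
    return paths
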