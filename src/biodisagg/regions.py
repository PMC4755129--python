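"""Country-to-region disaggregation schemes.

Regional environmental assessments (GEO, IPBES) partition the world's
countries into regions, each subdivided into subregions.  A scheme is a
table mapping ISO3 country codes to a (region, subregion) pair, plus a
small set of *special units* that are not countries at all — the high
seas ("Areas Beyond National Jurisdiction", ABNJ) and, for IPBES, an
"Excluded" unit (the Antarctic).  Two transcribed schemes ship with the
package and any user table with the same columns is accepted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "UnitLevel",
    "SchemeEntry",
    "RegionScheme",
    "SchemeValidationError",
    "UnknownUnitError",
    "load_scheme",
    "packaged_scheme",
]


class SchemeValidationError(ValueError):
    """Raised when a regionalization table violates the scheme invariants."""


class UnknownUnitError(KeyError):
    """Raised when a country code or unit label is absent from a scheme."""


class UnitLevel(str, enum.Enum):
    REGION = "region"
    SUBREGION = "subregion"


@dataclass(frozen=True)
class SchemeEntry:
    country_name: str
    iso3: str
    region: str
    subregion: str


@dataclass
class RegionScheme:
    """A validated country → (region, subregion) mapping.

    ``special_units`` are units with no member countries (e.g. ABNJ);
    they appear at both levels, after all country-derived units.
    """

    name: str
    entries: list[SchemeEntry]
    special_units: list[str] = field(default_factory=list)

    _by_code: dict[str, SchemeEntry] = field(init=False, repr=False)
    _region_of_subregion: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_code: dict[str, SchemeEntry] = {}
        sub_to_region: dict[str, str] = {}
        for e in self.entries:
            if e.iso3 in by_code:
                raise SchemeValidationError(
                    f"duplicate ISO3 code {e.iso3!r} in scheme {self.name!r}"
                )
            by_code[e.iso3] = e
            prev = sub_to_region.get(e.subregion)
            if prev is not None and prev != e.region:
                raise SchemeValidationError(
                    f"subregion {e.subregion!r} maps to two regions "
                    f"({prev!r} and {e.region!r}) in scheme {self.name!r}"
                )
            sub_to_region[e.subregion] = e.region
        self._by_code = by_code
        self._region_of_subregion = sub_to_region

    # -- lookups -----------------------------------------------------------

    def unit_of(self, country_code: str, level: UnitLevel | str) -> str:
        """Region or subregion label for one country code."""
        level = UnitLevel(level)
        try:
            e = self._by_code[country_code]
        except KeyError:
            raise UnknownUnitError(
                f"country code {country_code!r} not in scheme {self.name!r}"
            ) from None
        return e.region if level is UnitLevel.REGION else e.subregion

    def units(self, level: UnitLevel | str, include_special: bool = True) -> list[str]:
        """Unit labels at a level, in first-appearance order, special units last."""
        level = UnitLevel(level)
        out: list[str] = []
        seen: set[str] = set()
        for e in self.entries:
            u = e.region if level is UnitLevel.REGION else e.subregion
            if u not in seen:
                seen.add(u)
                out.append(u)
        if include_special:
            out.extend(u for u in self.special_units if u not in seen)
        return out

    def members(self, unit: str, level: UnitLevel | str) -> frozenset[str]:
        """ISO3 codes belonging to a unit. Special units have no members;
        their occurrence records carry the unit label itself."""
        level = UnitLevel(level)
        if unit in self.special_units:
            return frozenset()
        codes = frozenset(
            e.iso3
            for e in self.entries
            if (e.region if level is UnitLevel.REGION else e.subregion) == unit
        )
        if not codes:
            raise UnknownUnitError(
                f"unit {unit!r} not in scheme {self.name!r} at level {level.value}"
            )
        return codes

    def has_unit(self, unit: str, level: UnitLevel | str) -> bool:
        return unit in self.special_units or unit in self.units(level, include_special=False)

    def region_of_subregion(self, subregion: str) -> str:
        try:
            return self._region_of_subregion[subregion]
        except KeyError:
            raise UnknownUnitError(f"subregion {subregion!r} not in scheme") from None

    def __contains__(self, country_code: str) -> bool:
        return country_code in self._by_code

    @property
    def country_codes(self) -> list[str]:
        return [e.iso3 for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        """Serialize back to the tabular form accepted by :func:`load_scheme`."""
        rows = [
            (e.country_name, e.iso3, e.region, e.subregion) for e in self.entries
        ] + [(u, "", u, "") for u in self.special_units]
        return pd.DataFrame(rows, columns=["country_name", "iso3", "region", "subregion"])

    def summary(self) -> pd.DataFrame:
        """One row per unit: (unit, level, n_countries)."""
        rows = []
        for level in UnitLevel:
            for u in self.units(level):
                rows.append((u, level.value, len(self.members(u, level))))
        return pd.DataFrame(rows, columns=["unit", "level", "n_countries"])


def _clean(x: object) -> str:
    return "" if x is None or (isinstance(x, float) and pd.isna(x)) else str(x).strip()


def load_scheme(
    table: pd.DataFrame | Iterable[Mapping[str, str]] | str | Path,
    name: str = "scheme",
) -> RegionScheme:
    """Build a validated :class:`RegionScheme` from a regionalization table.

    The table needs columns ``iso3``, ``region``, ``subregion`` and
    optionally ``country_name``.  Rows with an empty ``iso3`` declare a
    special unit whose label is taken from the ``region`` column.  Labels
    are stripped of surrounding whitespace but case is preserved.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, dtype=str, keep_default_na=False)
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.DataFrame(list(table))
    missing = {"iso3", "region", "subregion"} - set(df.columns)
    if missing:
        raise SchemeValidationError(f"scheme table missing columns: {sorted(missing)}")

    entries: list[SchemeEntry] = []
    special: list[str] = []
    for _, row in df.iterrows():
        code = _clean(row["iso3"])
        region = _clean(row["region"])
        subregion = _clean(row["subregion"])
        cname = _clean(row["country_name"]) if "country_name" in df.columns else code
        if not code:
            label = region or cname
            if not label:
                raise SchemeValidationError("special-unit row with no label")
            if label not in special:
                special.append(label)
            continue
        entries.append(SchemeEntry(cname or code, code, region, subregion))
    return RegionScheme(name=name, entries=entries, special_units=special)


def packaged_scheme(name: str) -> RegionScheme:
    """Load one of the bundled schemes ("GEO" or "IPBES")."""
    fname = {"GEO": "geo_scheme.csv", "IPBES": "ipbes_scheme.csv"}.get(name.upper())
    if fname is None:
        raise UnknownUnitError(f"no packaged scheme named {name!r}")
    with resources.files("biodisagg.data").joinpath(fname).open("r") as f:
        df = pd.read_csv(f, dtype=str, keep_default_na=False)
    return load_scheme(df, name=name.upper())
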