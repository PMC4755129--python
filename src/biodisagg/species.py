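"""Species occurrence, endemism and threatened-fraction tabulation.

Red List assessments place each species into one of nine mutually
exclusive categories: EX (Extinct), EW (Extinct in the Wild), CR
(Critically Endangered, optionally flagged Possibly Extinct / Possibly
Extinct in the Wild), EN (Endangered), VU (Vulnerable), NT (Near
Threatened), LC (Least Concern), DD (Data Deficient) and NE (Not
Evaluated).  "Threatened" means CR+EN+VU.  Because it is unknown whether
DD species are threatened, the percentage threatened in a species set is
reported as a best estimate bracketed by a lower and an upper bound:

    lower = 100 * (CR+EN+VU) / (assessed - EX)          # no DD threatened
    best  = 100 * (CR+EN+VU) / (assessed - EX - DD)     # DD like the rest
    upper = 100 * (CR+EN+VU+DD) / (assessed - EX)       # all DD threatened

where ``assessed`` counts every category except NE.  A species *occurs*
in a unit if it has an occurrence record in at least one member country
(or in the special unit itself) after discarding vagrant,
uncertain-origin and introduced records; it is *endemic* to the unit if
its filtered occurrences fall entirely inside the unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .regions import RegionScheme, UnitLevel, UnknownUnitError

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "ASSESSED_CATEGORIES",
    "THREATENED",
    "EXCLUDED_ORIGINS",
    "ThreatSummary",
    "MissingAssessmentError",
    "normalize_origins",
    "filter_occurrences",
    "species_occurring",
    "species_endemic",
    "category_counts",
    "threat_bounds",
    "tabulate_units",
]

CATEGORIES = ("EX", "EW", "CR", "EN", "VU", "NT", "LC", "DD", "NE")
ASSESSED_CATEGORIES = ("EX", "EW", "CR", "EN", "VU", "NT", "LC", "DD")
THREATENED = ("CR", "EN", "VU")

#: occurrence origin classes that never establish occurrence or endemism
EXCLUDED_ORIGINS = frozenset({"vagrant", "uncertain", "introduced"})

#: default alias map from common raw origin spellings to canonical tokens
DEFAULT_ORIGIN_ALIASES: Mapping[str, str] = {
    "native": "native",
    "reintroduced": "native",  # not in the exclusion list; treated as native
    "vagrant": "vagrant",
    "introduced": "introduced",
    "uncertain": "uncertain",
    "origin uncertain": "uncertain",
    "presence uncertain": "uncertain",
}


class MissingAssessmentError(KeyError):
    """A species set contains ids with no assessment record."""


@dataclass
class ThreatSummary:
    """Per-category counts and the three threatened-percentage estimates."""

    counts: dict[str, int]
    total_assessed: int
    pct_lower: float | None
    pct_best: float | None
    pct_upper: float | None


def normalize_origins(
    origins: pd.Series, aliases: Mapping[str, str] | None = None
) -> pd.Series:
    """Map raw origin tokens to the canonical vocabulary.

    Unknown tokens default to ``native`` with a logged warning: only the
    three named classes (vagrant / uncertain / introduced) are ever
    excluded, so an unrecognised code must not silently drop a record.
    """
    amap = dict(DEFAULT_ORIGIN_ALIASES)
    if aliases:
        amap.update({k.strip().lower(): v for k, v in aliases.items()})
    lowered = origins.astype(str).str.strip().str.lower()
    out = lowered.map(amap)
    unknown = out.isna()
    if unknown.any():
        toks = sorted(lowered[unknown].unique())
        logger.warning(
            "%d occurrence records with unknown origin %s treated as native",
            int(unknown.sum()),
            toks,
        )
        out = out.fillna("native")
    return out


def filter_occurrences(
    occurrences: pd.DataFrame, aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Drop vagrant / uncertain-origin / introduced records."""
    occ = occurrences.copy()
    occ["origin"] = normalize_origins(occ["origin"], aliases)
    return occ[~occ["origin"].isin(EXCLUDED_ORIGINS)]


def _unit_codes(scheme: RegionScheme, unit: str, level: UnitLevel | str) -> frozenset[str]:
    if not scheme.has_unit(unit, level):
        raise UnknownUnitError(f"unit {unit!r} not in scheme {scheme.name!r}")
    if unit in scheme.special_units:
        return frozenset({unit})
    return scheme.members(unit, level)


def species_occurring(
    occurrences: pd.DataFrame,
    scheme: RegionScheme,
    unit: str,
    level: UnitLevel | str = UnitLevel.REGION,
    *,
    prefiltered: bool = False,
) -> set[str]:
    """Species with at least one qualifying occurrence in the unit.

    ``occurrences`` has columns species_id, unit_code, origin; unit_code
    is an ISO3 code or a special-unit label (e.g. "ABNJ").
    """
    codes = _unit_codes(scheme, unit, level)
    occ = occurrences if prefiltered else filter_occurrences(occurrences)
    return set(occ.loc[occ["unit_code"].isin(codes), "species_id"])


def species_endemic(
    occurrences: pd.DataFrame,
    scheme: RegionScheme,
    unit: str,
    level: UnitLevel | str = UnitLevel.REGION,
    *,
    prefiltered: bool = False,
) -> set[str]:
    """Species whose entire filtered occurrence set lies within the unit.

    Endemism to ABNJ is rejected (no species occurs only on the high
    seas); a species apparently endemic there indicates bad input and is
    dropped with a warning.
    """
    codes = _unit_codes(scheme, unit, level)
    occ = occurrences if prefiltered else filter_occurrences(occurrences)
    inside = species_occurring(occ, scheme, unit, level, prefiltered=True)
    if not inside:
        return set()
    outside = set(occ.loc[~occ["unit_code"].isin(codes), "species_id"])
    endemic = inside - outside
    if unit == "ABNJ" and endemic:
        logger.warning(
            "%d species appear endemic to ABNJ; rejected (high-seas-only "
            "occurrence is not expected)",
            len(endemic),
        )
        return set()
    return endemic


def category_counts(
    species_set: Iterable[str], assessments: pd.DataFrame
) -> dict[str, int]:
    """Count Red List categories over a species set.

    ``assessments`` has columns species_id, group, category (and
    optionally flag).  Every species in the set must have exactly one
    assessment row.
    """
    ids = set(species_set)
    sub = assessments[assessments["species_id"].isin(ids)]
    missing = ids - set(sub["species_id"])
    if missing:
        raise MissingAssessmentError(
            f"{len(missing)} species without assessment: {sorted(missing)[:10]}"
        )
    counts = {c: 0 for c in CATEGORIES}
    for cat, n in sub["category"].value_counts().items():
        if cat not in counts:
            raise ValueError(f"unknown Red List category {cat!r}")
        counts[cat] = int(n)
    return counts


def threat_bounds(
    counts: Mapping[str, int]
) -> tuple[float | None, float | None, float | None]:
    """Lower / best / upper percentage-threatened estimates.

    NE is excluded from the assessed total; EW stays in every
    denominator (only EX is subtracted).  A zero denominator yields
    ``None`` (reported as not-applicable, never an exception).
    """
    assessed = sum(int(counts.get(c, 0)) for c in ASSESSED_CATEGORIES)
    thr = sum(int(counts.get(c, 0)) for c in THREATENED)
    dd = int(counts.get("DD", 0))
    ex = int(counts.get("EX", 0))
    den_outer = assessed - ex
    den_inner = assessed - ex - dd
    lower = 100.0 * thr / den_outer if den_outer > 0 else None
    best = 100.0 * thr / den_inner if den_inner > 0 else None
    upper = 100.0 * (thr + dd) / den_outer if den_outer > 0 else None
    return lower, best, upper


def summarize(species_set: Iterable[str], assessments: pd.DataFrame) -> ThreatSummary:
    counts = category_counts(species_set, assessments)
    lower, best, upper = threat_bounds(counts)
    total = sum(counts[c] for c in ASSESSED_CATEGORIES)
    return ThreatSummary(counts, total, lower, best, upper)


ALL_GROUPS = "all"


def tabulate_units(
    scheme: RegionScheme,
    level: UnitLevel | str,
    assessments: pd.DataFrame,
    occurrences: pd.DataFrame,
    mode: str = "occurring",
    *,
    groups: list[str] | None = None,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per (unit, taxonomic group) plus an all-groups row.

    ``mode`` selects occurring or endemic species sets.  Columns: unit,
    level, group, one per category, total (assessed, NE excluded),
    pct_lower, pct_best, pct_upper.
    """
    if mode not in ("occurring", "endemic"):
        raise ValueError(f"mode must be 'occurring' or 'endemic', got {mode!r}")
    level = UnitLevel(level)
    occ = filter_occurrences(occurrences, aliases)
    pick = species_occurring if mode == "occurring" else species_endemic
    group_of = assessments.set_index("species_id")["group"]
    if groups is None:
        groups = list(dict.fromkeys(assessments["group"]))

    rows = []
    for unit in scheme.units(level):
        sp = pick(occ, scheme, unit, level, prefiltered=True)
        by_group = {g: set() for g in groups}
        for s in sp:
            g = group_of.get(s)
            if g in by_group:
                by_group[g].add(s)
        for g in [ALL_GROUPS, *groups]:
            members = sp if g == ALL_GROUPS else by_group[g]
            counts = category_counts(members, assessments)
            lower, best, upper = threat_bounds(counts)
            total = sum(counts[c] for c in ASSESSED_CATEGORIES)
            rows.append(
                {
                    "unit": unit,
                    "level": level.value,
                    "group": g,
                    **{c: counts[c] for c in CATEGORIES},
                    "total": total,
                    "pct_lower": lower,
                    "pct_best": best,
                    "pct_upper": upper,
                }
            )
    df = pd.DataFrame(rows)
    for col in ("pct_lower", "pct_best", "pct_upper"):
        df[col] = df[col].astype(float) if len(df) else df[col]
    return df
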