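"""Spatial downscaling of Red List Index change.

The Red List Index (RLI) tracks aggregate movement of a taxon through
the Red List categories.  Only *genuine* category changes — those caused
by real change in extinction risk, not by new knowledge or taxonomic
revision — enter the index.  A unit's contribution to the global annual
RLI change is

    value(u) = [ sum_s net_steps(s) * fraction(s, u) ] / years

where ``net_steps(s)`` sums a species' signed single-category moves
(-1 per move of increasing risk, +1 per move of decreasing risk),
``fraction(s, u)`` is the share of the species' range inside unit ``u``,
and ``years`` spans the assessment period.  Because a species' fractions
over one level's units sum to one, unit contributions sum exactly to the
global net annual change — downscaling partitions the global trend.

Category ordering for rank differences: LC < NT < VU < EN < CR <
{EW, EX, CR flagged Possibly Extinct or Possibly Extinct in the Wild}.
DD and NE are not rankable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .regions import RegionScheme, UnitLevel

logger = logging.getLogger(__name__)

__all__ = [
    "AssessmentPeriod",
    "CategoryChangeEvent",
    "NotRankableError",
    "MissingWeightError",
    "FractionSumError",
    "category_rank",
    "events_from_category_pair",
    "validate_fractions",
    "weighted_annual_change",
    "additivity_check",
]

FRACTION_TOL = 1e-6

_RANKS = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4, "EW": 5, "EX": 5}


class NotRankableError(ValueError):
    """DD or NE categories carry no position on the risk ordering."""


class MissingWeightError(KeyError):
    """A species with genuine changes has no range fractions."""


class FractionSumError(ValueError):
    """A species' range fractions over a level's units do not sum to 1."""


@dataclass(frozen=True)
class AssessmentPeriod:
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("assessment period must have positive span")

    @property
    def years(self) -> int:
        return self.end_year - self.start_year


@dataclass(frozen=True)
class CategoryChangeEvent:
    """One single-category move; step=-1 increasing risk, +1 decreasing."""

    species_id: str
    step: int

    def __post_init__(self) -> None:
        if self.step not in (-1, 1):
            raise ValueError("step must be -1 or +1")


def category_rank(category: str, flag: str | None = None) -> int:
    """Ordinal on the risk ordering; CR flagged PE/PEW ranks with EW/EX."""
    if category in ("DD", "NE"):
        raise NotRankableError(f"category {category!r} has no rank")
    if category not in _RANKS:
        raise NotRankableError(f"unknown category {category!r}")
    if flag not in (None, "", "none", "PE", "PEW"):
        raise ValueError(f"unknown flag {flag!r}")
    if flag in ("PE", "PEW"):
        if category != "CR":
            raise ValueError("PE/PEW flags are valid only with CR")
        return 5
    return _RANKS[category]


def events_from_category_pair(
    cat_start: str,
    cat_end: str,
    genuine: bool,
    flag_start: str | None = None,
    flag_end: str | None = None,
    species_id: str = "",
) -> list[CategoryChangeEvent]:
    """Decompose a recorded category pair into unit-step events.

    A multi-category move yields one event per category crossed, all with
    the same sign (risk increase → -1).  Non-genuine pairs yield nothing.
    """
    if not genuine:
        return []
    r0 = category_rank(cat_start, flag_start)
    r1 = category_rank(cat_end, flag_end)
    if r1 == r0:
        return []
    step = -1 if r1 > r0 else 1
    return [CategoryChangeEvent(species_id, step) for _ in range(abs(r1 - r0))]


def validate_fractions(fractions: pd.DataFrame, species_ids=None) -> None:
    """Check per-species fraction sums are 1 within tolerance.

    ``fractions`` has columns species_id, unit, fraction (one level at a
    time).  Deviations beyond 1e-6 raise rather than being silently
    renormalized.
    """
    sums = fractions.groupby("species_id")["fraction"].sum()
    if species_ids is not None:
        sums = sums[sums.index.isin(set(species_ids))]
    bad = sums[(sums - 1.0).abs() > FRACTION_TOL]
    if len(bad):
        raise FractionSumError(
            f"range fractions do not sum to 1 for {len(bad)} species, e.g. "
            + ", ".join(f"{s}={v:.8f}" for s, v in bad.head(5).items())
        )


def weighted_annual_change(
    events: pd.DataFrame,
    range_fractions: pd.DataFrame,
    period: AssessmentPeriod,
    scheme: RegionScheme,
    level: UnitLevel | str = UnitLevel.REGION,
    *,
    check_fractions: bool = True,
) -> pd.Series:
    """Per-unit weighted annual RLI change, indexed by unit label.

    ``events`` has columns species_id, step (pre-decomposed genuine
    single-category moves); ``range_fractions`` has species_id, unit,
    fraction for the requested level.  Every unit of the scheme appears
    in the result (zero where no weighted change falls).
    """
    level = UnitLevel(level)
    units = scheme.units(level)
    out = pd.Series(0.0, index=pd.Index(units, name="unit"))
    if len(events) == 0:
        return out

    net = events.groupby("species_id")["step"].sum()
    net = net[net != 0]
    if len(net) == 0:
        return out

    frac = range_fractions[range_fractions["species_id"].isin(set(net.index))]
    missing = set(net.index) - set(frac["species_id"])
    if missing:
        raise MissingWeightError(
            f"{len(missing)} species with genuine changes lack range "
            f"fractions: {sorted(missing)[:10]}"
        )
    if check_fractions:
        validate_fractions(frac)

    weighted = frac["fraction"].to_numpy() * net.reindex(frac["species_id"]).to_numpy()
    per_unit = pd.Series(weighted).groupby(frac["unit"].to_numpy()).sum()
    out = out.add(per_unit / period.years, fill_value=0.0)
    return out.reindex(units).fillna(0.0).rename_axis("unit")


def additivity_check(
    contributions: pd.Series, events: pd.DataFrame, period: AssessmentPeriod
) -> float:
    """Residual between summed unit contributions and the global change.

    Zero (to ~1e-9) whenever every species' fractions sum to one; a
    nonzero residual flags unnormalized or missing weights.
    """
    global_change = float(events["step"].sum()) / period.years if len(events) else 0.0
    return float(contributions.sum()) - global_change


def tabulate_rli(
    events: pd.DataFrame,
    range_fractions: pd.DataFrame,
    period: AssessmentPeriod,
    scheme: RegionScheme,
    *,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Both levels, optionally split by taxon group.

    ``groups`` maps species_id → group label; when given, one block of
    rows per group is produced, else a single "all" block.  Columns:
    unit, level, taxon, weighted_annual_change.
    """
    rows = []
    if groups is None:
        blocks = [("all", events)]
    else:
        blocks = [
            (g, events[events["species_id"].map(groups).eq(g)])
            for g in dict.fromkeys(groups)
        ]
    for level in UnitLevel:
        frac_lvl = (
            range_fractions[range_fractions["level"] == level.value]
            if "level" in range_fractions.columns
            else range_fractions
        )
        for g, ev in blocks:
            contrib = weighted_annual_change(ev, frac_lvl, period, scheme, level)
            for unit, value in contrib.items():
                rows.append(
                    {
                        "unit": unit,
                        "level": level.value,
                        "taxon": g,
                        "weighted_annual_change": value,
                    }
                )
    return pd.DataFrame(rows)
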